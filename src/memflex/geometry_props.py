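"""Membrane geometry observables.

Bilayer thickness, area per lipid, leaflet density profiles with Gaussian
model fitting, lateral mean-squared displacement and the diffusion
coefficient. All lengths in nm, times in ps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DegenerateBilayerError, EmptyInputError, FitError
from .trajectory_model import (
    BeadFrame,
    LeafletAssignment,
    Trajectory,
    minimum_image,
    require_square_box,
)


# ---------------------------------------------------------------------------
# thickness and area per lipid
# ---------------------------------------------------------------------------

def thickness_series(traj: Trajectory, assignment: LeafletAssignment) -> np.ndarray:
    """Per-frame bilayer thickness: mean top head z minus mean bottom head z."""
    head_z = traj.head_z()
    top = head_z[:, assignment.top_mask]
    bot = head_z[:, assignment.bottom_mask]
    if top.shape[1] == 0 or bot.shape[1] == 0:
        raise DegenerateBilayerError("one leaflet is empty")
    return top.mean(axis=1) - bot.mean(axis=1)


def thickness(traj: Trajectory, assignment: LeafletAssignment) -> float:
    """Bilayer thickness D_B averaged over all frames (nm)."""
    return float(thickness_series(traj, assignment).mean())


def area_per_lipid(frame: BeadFrame, assignment: LeafletAssignment) -> float:
    """Area per lipid: mean over the two leaflets of l_cell^2 / n_leaflet.

    For symmetric leaflets this equals the lateral cell area divided by the
    lipids in one monolayer.
    """
    require_square_box(frame.box)
    n_top, n_bot = assignment.n_top, assignment.n_bottom
    if n_top == 0 or n_bot == 0:
        raise DegenerateBilayerError("one leaflet is empty")
    area = float(frame.box[0]) ** 2
    return 0.5 * (area / n_top + area / n_bot)


def apl_series(traj: Trajectory, assignment: LeafletAssignment) -> np.ndarray:
    for f in range(traj.n_frames):
        require_square_box(traj.box[f])
    area = traj.box[:, 0] ** 2
    return 0.5 * (area / assignment.n_top + area / assignment.n_bottom)


@dataclass
class GeometryResult:
    """Summary of membrane geometry for one trajectory."""

    D_B: float
    APL: float
    D_B_series: np.ndarray
    APL_series: np.ndarray
    l_cell: float
    n_top: int
    n_bottom: int

    def to_dict(self) -> dict:
        return {
            "D_B_nm": self.D_B,
            "APL_nm2": self.APL,
            "l_cell_nm": self.l_cell,
            "n_lipids_per_leaflet": {"top": self.n_top, "bottom": self.n_bottom},
            "ratio_DB_over_APL": self.D_B / self.APL,
        }


def geometry_summary(traj: Trajectory, assignment: LeafletAssignment) -> GeometryResult:
    db = thickness_series(traj, assignment)
    apl = apl_series(traj, assignment)
    return GeometryResult(
        D_B=float(db.mean()), APL=float(apl.mean()),
        D_B_series=db, APL_series=apl,
        l_cell=float(traj.box[0, 0]),
        n_top=assignment.n_top, n_bottom=assignment.n_bottom,
    )


# ---------------------------------------------------------------------------
# density profile and Gaussian model
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Head-bead number density vs z relative to the frame midplane.

    ``rho`` is in nm^-3 per bin; its integral over z equals
    n_leaflet / A_o (nm^-2).
    """

    z: np.ndarray           # bin centers, nm
    rho: np.ndarray         # nm^-3
    bin_width: float
    area: float             # lateral area, nm^2
    n_frames: int
    leaflet: str

    def integral(self) -> float:
        return float(np.sum(self.rho) * self.bin_width)


@dataclass
class DensityModel:
    """Gaussian leaflet density: rho_o * exp(-(z - sign*d/2)^2 / 2a) / sqrt(2 pi a)."""

    rho_o: float   # nm^-2
    d: float       # nm
    a: float       # nm^2
    sign: int      # +1 top, -1 bottom
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.rho_o <= 0 or self.d <= 0 or self.a <= 0:
            raise FitError(
                f"invalid density model (rho_o={self.rho_o}, d={self.d}, a={self.a})"
            )

    @property
    def center(self) -> float:
        return self.sign * self.d / 2.0

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        return self.rho_o * np.exp(-(z - self.center) ** 2 / (2 * self.a)) / np.sqrt(
            2 * np.pi * self.a
        )


def density_profile(
    traj: Trajectory,
    assignment: LeafletAssignment,
    leaflet: str,
    bin_width: float = 0.02,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Histogram of head-bead z (relative to the per-frame midplane).

    Normalized by lateral area, bin width and frame count so that the z
    integral equals n_leaflet / A_o.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin width must be positive")
    if leaflet not in ("top", "bottom"):
        raise ConfigurationError(f"unknown leaflet {leaflet!r}")
    mask = assignment.top_mask if leaflet == "top" else assignment.bottom_mask
    head_z = traj.head_z()
    rel = head_z - head_z.mean(axis=1, keepdims=True)
    vals = rel[:, mask].ravel()
    if z_range is None:
        lo, hi = vals.min(), vals.max()
        pad = 3 * bin_width
        z_range = (lo - pad, hi + pad)
    n_bins = max(int(np.ceil((z_range[1] - z_range[0]) / bin_width)), 1)
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    area = float(traj.box[0, 0] * traj.box[0, 1])
    rho = counts / (area * bin_width * traj.n_frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, rho, bin_width, area, traj.n_frames, leaflet)


def fit_density_gaussian(profile: DensityProfile, sign: int) -> DensityModel:
    """Least-squares Gaussian fit of a leaflet density profile."""
    occupied = profile.rho > 0
    if int(occupied.sum()) < 5:
        raise FitError(
            f"profile has only {int(occupied.sum())} occupied bins (>=5 required)"
        )
    z, rho = profile.z, profile.rho
    # moment-based initial guess
    w = rho.sum()
    mu0 = float(np.sum(rho * z) / w)
    var0 = float(np.sum(rho * (z - mu0) ** 2) / w)
    rho_o0 = float(w * profile.bin_width)

    def model(zz, rho_o, mu, a):
        return rho_o * np.exp(-(zz - mu) ** 2 / (2 * a)) / np.sqrt(2 * np.pi * a)

    try:
        popt, _ = curve_fit(
            model, z, rho, p0=[rho_o0, mu0, max(var0, 1e-6)], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"density fit did not converge: {exc}") from exc
    rho_o, mu, a = popt
    resid = float(np.linalg.norm(rho - model(z, *popt)))
    if rho_o <= 0 or a <= 0 or mu * sign <= 0:
        raise FitError(
            f"density fit degenerate: rho_o={rho_o:.4g}, center={mu:.4g}, a={a:.4g} "
            f"(residual {resid:.4g})"
        )
    return DensityModel(rho_o=float(rho_o), d=float(2 * abs(mu)), a=float(a),
                        sign=sign, residual_norm=resid)


# ---------------------------------------------------------------------------
# lateral MSD and diffusion
# ---------------------------------------------------------------------------

@dataclass
class MSDResult:
    """Lateral MSD averaged over lipids and time origins."""

    lags: np.ndarray           # ps
    msd: np.ndarray            # nm^2
    per_lipid: np.ndarray      # (n_lags, n_lipids)
    dt: float

    def __post_init__(self):
        assert abs(self.msd[0]) < 1e-12


def unwrap_lateral(traj: Trajectory) -> np.ndarray:
    """Unwrapped head-bead lateral coordinates, shape (F, M, 2)."""
    xy = traj.head_xy()
    steps = minimum_image(np.diff(xy, axis=0), traj.box[1:, None, :2])
    return np.concatenate([xy[:1], xy[:1] + np.cumsum(steps, axis=0)], axis=0)


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Windowed-average MSD over all time origins via FFT.

    ``x`` has shape (F, M); returns (F, M) with row m the MSD at lag m.
    """
    F = x.shape[0]
    nfft = 1 << (2 * F - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:F].real
    sq = x ** 2
    ssum = sq.sum(axis=0)
    # S1(m) = sum_{t<F-m} (x_t^2 + x_{t+m}^2), computed by prefix sums
    csum = np.cumsum(sq, axis=0)
    rsum = np.cumsum(sq[::-1], axis=0)
    m = np.arange(F)
    s1 = np.empty_like(acf)
    s1[0] = 2 * ssum
    for k in range(1, F):
        s1[k] = (csum[F - k - 1]) + (rsum[F - k - 1])
    counts = (F - m)[:, None]
    return (s1 - 2 * acf) / counts


def lateral_msd(traj: Trajectory) -> MSDResult:
    """Lateral MSD(tau) averaged over lipids and all time origins.

    Coordinates are unwrapped across periodic images internally; the input
    should have had its overall lateral center-of-mass motion removed.
    """
    if traj.n_frames < 2:
        raise EmptyInputError("MSD requires at least 2 frames")
    if not traj.com_removed:
        warnings.warn(
            "lateral_msd called on a trajectory without com removal",
            RuntimeWarning, stacklevel=2,
        )
    xy = unwrap_lateral(traj)
    per = _msd_fft(xy[:, :, 0]) + _msd_fft(xy[:, :, 1])
    lags = np.arange(traj.n_frames) * traj.dt
    msd = per.mean(axis=1)
    msd[0] = 0.0
    per[0] = 0.0
    return MSDResult(lags=lags, msd=msd, per_lipid=per, dt=traj.dt)


@dataclass
class DiffusionResult:
    """Lateral diffusion coefficient from the MSD slope / 4."""

    D: float                   # nm^2/ps
    slope: float               # nm^2/ps
    stderr: float              # nm^2/ps, on D
    fit_window: tuple
    r_squared: float
    exponent: float | None = None  # log-log MSD slope diagnostic (~1 diffusive)
    warnings: list = field(default_factory=list)

    @property
    def D_cm2_per_s(self) -> float:
        # 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s
        return self.D * 1e-2


def diffusion_coefficient(
    msd: MSDResult, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionResult:
    """Fit a line to MSD(tau) over a fractional lag window; D = slope / 4."""
    n = len(msd.lags)
    lo = max(int(fit_window[0] * n), 1)
    hi = max(int(fit_window[1] * n), lo + 2)
    if hi > n:
        raise ConfigurationError("fit window outside MSD series")
    t = msd.lags[lo:hi]
    y = msd.msd[lo:hi]
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(coef[1])
    pred = X @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # SE from the spread of independent per-lipid slopes
    M = msd.per_lipid.shape[1]
    slopes = np.linalg.lstsq(X, msd.per_lipid[lo:hi], rcond=None)[0][1]
    se = float(np.std(slopes, ddof=1) / np.sqrt(M) / 4.0) if M > 1 else 0.0
    warns = []
    if slope < 0:
        warns.append("negative MSD slope; D reported with its sign")
        warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
    # linearity diagnostic: log-log slope should be ~1 for diffusive motion
    exponent = None
    if np.all(y > 0):
        exponent = float(np.polyfit(np.log(t), np.log(y), 1)[0])
        if abs(exponent - 1.0) > 0.3:
            warns.append(
                f"poor linear fit to MSD (log-log exponent {exponent:.2f}, "
                "expected ~1 for diffusive motion)"
            )
    if ss_tot > 0 and r2 < 0.9:
        warns.append(f"poor linear fit to MSD (R^2 = {r2:.3f})")
    return DiffusionResult(
        D=slope / 4.0, slope=slope, stderr=se,
        fit_window=(lo, hi), r_squared=r2, exponent=exponent, warnings=warns,
    )
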