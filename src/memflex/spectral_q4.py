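"""Undulation spectrum and the q^-4 bending-modulus fit.

Fourier convention (shared with the synthetic generator): for discrete
wavevectors q = 2*pi*(n_x, n_y)/L on the periodic square box,

    h(q) = (1/N) * sum_j z_j exp(-i q . r_j)

over the head beads of both leaflets, with the mid-surface height z_j
taken as head z minus the leaflet mean (per frame). Under this convention
the equilibrium spectrum of a membrane with bending modulus kappa_b and
tension tau is

    <|h(q)|^2> = k_B T / (A (tau q^2 + kappa_b q^4)),   A = l_cell^2,

with kappa_b in units of k_B T and tau in k_B T / nm^2 (reduced units,
k_B T = 1 internally).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyInputError, FitError
from .trajectory_model import (
    KB,
    BeadFrame,
    LeafletAssignment,
    Trajectory,
    require_square_box,
)


# ---------------------------------------------------------------------------
# mode bookkeeping
# ---------------------------------------------------------------------------

def mode_indices(n_max: int) -> np.ndarray:
    """All integer (n_x, n_y) with 0 < n_x^2 + n_y^2 <= n_max^2."""
    if n_max < 1:
        raise ConfigurationError("n_max must be >= 1")
    n = np.arange(-n_max, n_max + 1)
    nx, ny = np.meshgrid(n, n, indexing="ij")
    n2 = nx ** 2 + ny ** 2
    keep = (n2 > 0) & (n2 <= n_max ** 2)
    return np.column_stack([nx[keep], ny[keep]])


def shell_indices(n_shells: int) -> tuple[np.ndarray, list[int]]:
    """Mode indices covering the ``n_shells`` lowest nonzero |q| shells.

    Returns (nvecs, shell_n2) where shell_n2 lists the integer n^2 value of
    each retained shell in increasing order.
    """
    n_max = 1
    while True:
        nvecs = mode_indices(n_max)
        n2 = np.unique(np.sum(nvecs ** 2, axis=1))
        if len(n2) >= n_shells:
            shells = [int(v) for v in n2[:n_shells]]
            keep = np.isin(np.sum(nvecs ** 2, axis=1), shells)
            return nvecs[keep], shells
        n_max += 1


def fourier_modes(xy: np.ndarray, z: np.ndarray, L: float, nvecs: np.ndarray) -> np.ndarray:
    """Direct nonuniform Fourier sum h(q) = (1/N) sum_j z_j exp(-i q.r_j)."""
    q = 2 * np.pi / L * np.asarray(nvecs, dtype=float)  # (M, 2)
    phase = xy @ q.T                                    # (N, M)
    return np.exp(-1j * phase).T @ z / len(z)


# ---------------------------------------------------------------------------
# per-frame height modes
# ---------------------------------------------------------------------------

def _mid_surface_heights(
    head_xy: np.ndarray, head_z: np.ndarray, top_mask: np.ndarray,
    leaflet_center: bool,
) -> np.ndarray:
    """Head z with the mean removed (per leaflet by default).

    Removing the mean per leaflet cancels the +-d/2 leaflet offsets exactly,
    which keeps the pooled Fourier sum free of offset leakage even when the
    lateral positions are far from a regular lattice.
    """
    z = head_z.copy()
    if leaflet_center:
        z[top_mask] -= z[top_mask].mean()
        z[~top_mask] -= z[~top_mask].mean()
    else:
        z -= z.mean()
    return z


def height_modes(
    frame: BeadFrame,
    assignment: LeafletAssignment,
    n_max: int,
    leaflet_center: bool = True,
    nvecs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Height modes h(q) of a single frame.

    Returns ``(nvecs, h)`` where ``nvecs`` are integer mode indices and
    ``h`` the complex amplitudes. Hermitian symmetry h(-q) = conj(h(q))
    holds by construction because the height field is real.
    """
    require_square_box(frame.box)
    if nvecs is None:
        nvecs = mode_indices(n_max)
    xy = frame.head_positions()[:, :2]
    z = _mid_surface_heights(
        xy, frame.head_positions()[:, 2], assignment.top_mask, leaflet_center
    )
    return nvecs, fourier_modes(xy, z, frame.l_cell, nvecs)


# ---------------------------------------------------------------------------
# ensemble spectrum
# ---------------------------------------------------------------------------

@dataclass
class HeightSpectrum:
    """Ensemble-averaged undulation spectrum on the discrete q lattice."""

    nvecs: np.ndarray        # (M, 2) integer mode indices
    q: np.ndarray            # (M, 2) nm^-1
    qmag: np.ndarray         # (M,)
    S: np.ndarray            # (M,) <|h(q)|^2>, nm^2
    area: float              # projected area l_cell^2, nm^2
    temperature: float       # K
    n_frames: int

    def shell_average(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Average S over modes of equal |q|; returns (q, S, counts)."""
        n2 = np.sum(self.nvecs ** 2, axis=1)
        shells = np.unique(n2)
        qs = np.empty(len(shells))
        ss = np.empty(len(shells))
        cnt = np.empty(len(shells), dtype=int)
        for i, s in enumerate(shells):
            m = n2 == s
            qs[i] = self.qmag[m].mean()
            ss[i] = self.S[m].mean()
            cnt[i] = int(m.sum())
        return qs, ss, cnt

    def to_table(self) -> np.ndarray:
        """(M, 4) array of (qx, qy, |q|, S) for CSV export."""
        return np.column_stack([self.q, self.qmag, self.S])


def average_spectrum(
    traj: Trajectory,
    assignment: LeafletAssignment,
    n_max: int = 4,
    leaflet_center: bool = True,
    nvecs: np.ndarray | None = None,
) -> HeightSpectrum:
    """Frame-averaged undulation spectrum <|h(q)|^2>."""
    if traj.n_frames < 1:
        raise EmptyInputError("spectrum requires at least one frame")
    require_square_box(traj.box[0])
    if not np.allclose(traj.box[:, 0], traj.box[0, 0]) or not np.allclose(
        traj.box[:, 1], traj.box[0, 1]
    ):
        raise ConfigurationError(
            "fluctuating lateral box not supported by the fixed-lattice spectrum"
        )
    if nvecs is None:
        nvecs = mode_indices(n_max)
    L = float(traj.box[0, 0])
    qvecs = 2 * np.pi / L * nvecs.astype(float)

    head_xy = traj.head_xy()          # (F, M, 2)
    head_z = traj.head_z()            # (F, M)
    top = assignment.top_mask
    z = head_z.copy()
    if leaflet_center:
        z[:, top] -= z[:, top].mean(axis=1, keepdims=True)
        z[:, ~top] -= z[:, ~top].mean(axis=1, keepdims=True)
    else:
        z -= z.mean(axis=1, keepdims=True)

    static_xy = bool(np.array_equal(head_xy[0], head_xy[-1])) and bool(
        np.array_equal(head_xy[0], head_xy[traj.n_frames // 2])
    )
    if static_xy:
        phase = head_xy[0] @ qvecs.T
        E = np.exp(-1j * phase)                      # (N, M)
        H = (z @ E) / head_xy.shape[1]               # (F, M)
        S = np.mean(np.abs(H) ** 2, axis=0)
    else:
        acc = np.zeros(len(nvecs))
        for f in range(traj.n_frames):
            h = fourier_modes(head_xy[f], z[f], L, nvecs)
            acc += np.abs(h) ** 2
        S = acc / traj.n_frames
    return HeightSpectrum(
        nvecs=nvecs, q=qvecs, qmag=np.linalg.norm(qvecs, axis=1), S=S,
        area=L * L, temperature=traj.temperature, n_frames=traj.n_frames,
    )


# ---------------------------------------------------------------------------
# modulus estimate container (shared by all three methods)
# ---------------------------------------------------------------------------

@dataclass
class ModulusEstimate:
    """A bending-modulus estimate with fit diagnostics.

    ``kappa`` is in units of k_B T; :meth:`kappa_joules` converts using the
    trajectory temperature.
    """

    method: str                       # 'q4' | 'bwdcf' | 'rsf'
    kappa: float                      # k_B T
    kappa_se: float = 0.0
    tension: float | None = None      # k_B T / nm^2 (q4 tension fit / gamma_o)
    tension_se: float | None = None
    slope: float | None = None        # log-log slope diagnostic (q4)
    window: dict = field(default_factory=dict)
    temperature: float | None = None  # K
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def kappa_joules(self, temperature: float | None = None) -> float:
        T = temperature if temperature is not None else self.temperature
        if T is None or T <= 0:
            raise ConfigurationError("temperature required for unit conversion")
        return self.kappa * KB * T

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "kappa_kBT": self.kappa,
            "kappa_se_kBT": self.kappa_se,
            "window": self.window,
            "warnings": list(self.warnings),
        }
        if self.tension is not None:
            out["tension_kBT_per_nm2"] = self.tension
            out["tension_se_kBT_per_nm2"] = self.tension_se
        if self.slope is not None:
            out["loglog_slope"] = self.slope
        if self.temperature is not None and self.temperature > 0:
            out["temperature_K"] = self.temperature
            out["kappa_J"] = self.kappa_joules()
        out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# q^-4 fit
# ---------------------------------------------------------------------------

def fit_q4(
    spectrum: HeightSpectrum,
    n_shells: int = 5,
    q_window: tuple[float, float] | None = None,
    include_tension: bool = False,
    slope_tolerance: float = 0.5,
) -> ModulusEstimate:
    """Extract the bending modulus from an undulation spectrum.

    Default route: kappa = mean over the fit window of 1 / (A S(q) q^4)
    (reduced units, k_B T = 1), with the log-log slope reported as a
    diagnostic (expected ~ -4). With ``include_tension`` the full spectrum
    model is inverted: 1/(A S q^2) = tau + kappa q^2 is fit linearly in q^2,
    returning (kappa, tau).
    """
    qs, ss, cnt = spectrum.shell_average()
    if q_window is not None:
        keep = (qs >= q_window[0]) & (qs <= q_window[1])
        qs, ss, cnt = qs[keep], ss[keep], cnt[keep]
    else:
        qs, ss, cnt = qs[:n_shells], ss[:n_shells], cnt[:n_shells]
    if len(qs) < 3:
        raise FitError(f"fit window contains only {len(qs)} shells (>=3 required)")
    if np.any(ss <= 0):
        raise FitError("non-positive spectral values in the fit window")
    A = spectrum.area
    warns: list[str] = []

    slope, _ = np.polyfit(np.log(qs), np.log(ss), 1)
    slope = float(slope)
    if abs(slope + 4.0) > slope_tolerance:
        warns.append(
            f"log-log slope {slope:.3f} deviates from -4 by more than "
            f"{slope_tolerance}"
        )
        warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)

    window = {"n_shells": len(qs), "q_min": float(qs[0]), "q_max": float(qs[-1])}
    if include_tension:
        y = 1.0 / (A * ss * qs ** 2)
        X = np.column_stack([np.ones_like(qs), qs ** 2])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        tau, kappa = float(coef[0]), float(coef[1])
        dof = max(len(qs) - 2, 1)
        sigma2 = float(np.sum((y - X @ coef) ** 2)) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return ModulusEstimate(
            method="q4", kappa=kappa, kappa_se=float(np.sqrt(cov[1, 1])),
            tension=tau, tension_se=float(np.sqrt(cov[0, 0])),
            slope=slope, window=window, temperature=spectrum.temperature,
            warnings=warns,
        )
    kappas = 1.0 / (A * ss * qs ** 4)
    kappa = float(np.mean(kappas))
    se = float(np.std(kappas, ddof=1) / np.sqrt(len(kappas))) if len(kappas) > 1 else 0.0
    if kappa <= 0:
        raise FitError("non-positive bending modulus from q^-4 inversion")
    return ModulusEstimate(
        method="q4", kappa=kappa, kappa_se=se, slope=slope,
        window=window, temperature=spectrum.temperature, warnings=warns,
    )


def q4_modulus(
    traj: Trajectory,
    assignment: LeafletAssignment,
    n_shells: int = 5,
    include_tension: bool = False,
    leaflet_center: bool = True,
) -> ModulusEstimate:
    """Convenience wrapper: spectrum over the fit shells, then :func:`fit_q4`."""
    nvecs, _ = shell_indices(n_shells)
    spec = average_spectrum(
        traj, assignment, leaflet_center=leaflet_center, nvecs=nvecs, n_max=0
    )
    return fit_q4(spec, n_shells=n_shells, include_tension=include_tension)


# ---------------------------------------------------------------------------
# convergence vs analyzed time
# ---------------------------------------------------------------------------

def convergence_series(
    traj: Trajectory,
    assignment: LeafletAssignment,
    estimator,
    checkpoints,
) -> list[tuple[int, ModulusEstimate]]:
    """Recompute an estimate on frames [0, t) for each checkpoint.

    ``estimator`` is a callable ``(trajectory, assignment) -> ModulusEstimate``;
    ``checkpoints`` are frame counts within the trajectory.
    """
    out = []
    for t in checkpoints:
        if not (1 <= t <= traj.n_frames):
            raise ConfigurationError(f"checkpoint {t} outside trajectory")
        out.append((int(t), estimator(traj.slice(0, int(t)), assignment)))
    return out
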