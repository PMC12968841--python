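"""Synthetic equilibrium membrane ensembles with known ground truth.

Generates two-leaflet bead trajectories whose statistics follow the models
the estimators invert:

* undulation modes with variance k_B T / (A (tau q^2 + kappa q^4)) under
  the package Fourier convention (shared with :mod:`memflex.spectral_q4`);
* leaflet head densities that are Gaussians of width sqrt(a) centered at
  +-d/2 around the midplane;
* tilt directors following the local surface normal plus Gaussian noise
  (so pairwise splay is Gaussian);
* lateral 2D Gaussian-walk motion with known diffusion coefficient D.

Frames are independent equilibrium samples, NOT time-correlated dynamics
(except the lateral walk, which is Markovian by construction). Estimator
correctness depends only on the equilibrium distribution, but convergence
rates will look optimistic compared to real, correlated MD frames.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ParameterError
from .trajectory_model import BeadTable, Trajectory, write_h5


@dataclass
class SynthParams:
    """Ground-truth parameters of a synthetic membrane ensemble.

    ``kappa`` is in k_B T, ``tension`` in k_B T/nm^2, lengths in nm,
    ``D`` in nm^2/ps, ``tilt_sd`` is the per-component SD of the lateral
    director noise (geometric splay mode). ``splay_mode='direct'`` instead
    derives the tilt noise from a target (K_c, A_l).
    """

    L: float = 40.0
    n_lipids: int = 1024            # per leaflet; must be a perfect square
    kappa: float = 30.0             # k_B T
    tension: float = 0.0            # k_B T / nm^2
    d: float = 4.0                  # nm
    a: float = 0.09                 # nm^2
    tilt_sd: float = 0.08
    splay_mode: str = "geometric"   # 'geometric' | 'direct'
    K_c: float | None = None        # k_B T (direct mode)
    A_l: float | None = None        # nm^2 (direct mode)
    D: float = 0.0                  # nm^2 / ps
    temperature: float = 310.0      # K
    n_frames: int = 100
    dt: float = 100.0               # ps
    n_max: int = 4
    seed: int = 0
    species: tuple = ("LIP",)
    tail_length: float = 1.6        # nm, head-to-tail-centroid distance
    lz_factor: float = 5.0          # L_z = lz_factor * d

    def __post_init__(self):
        if self.kappa <= 0 or self.L <= 0 or self.n_max < 1:
            raise ParameterError("require kappa > 0, L > 0, n_max >= 1")
        if self.d <= 0 or self.a <= 0 or self.n_frames < 1:
            raise ParameterError("require d > 0, a > 0, n_frames >= 1")
        if self.splay_mode not in ("geometric", "direct"):
            raise ParameterError(f"unknown splay_mode {self.splay_mode!r}")
        if self.splay_mode == "direct" and (self.K_c is None or self.A_l is None):
            raise ParameterError("direct splay mode requires K_c and A_l")

    @property
    def area(self) -> float:
        return self.L * self.L


# ---------------------------------------------------------------------------
# height field
# ---------------------------------------------------------------------------

def _half_modes(n_max: int) -> np.ndarray:
    """Canonical half of the q lattice (n_y > 0, or n_y == 0 and n_x > 0)."""
    n = np.arange(-n_max, n_max + 1)
    nx, ny = np.meshgrid(n, n, indexing="ij")
    n2 = nx ** 2 + ny ** 2
    keep = (n2 > 0) & (n2 <= n_max ** 2) & ((ny > 0) | ((ny == 0) & (nx > 0)))
    return np.column_stack([nx[keep], ny[keep]])


def mode_variances(params: SynthParams, nvecs: np.ndarray) -> np.ndarray:
    """Target <|h(q)|^2> per mode: 1 / (A (tau q^2 + kappa q^4)), k_B T = 1."""
    q2 = (2 * np.pi / params.L) ** 2 * np.sum(nvecs ** 2, axis=1)
    return 1.0 / (params.area * (params.tension * q2 + params.kappa * q2 ** 2))


class HeightField:
    """One equilibrium realization of the undulation field.

    Stores complex amplitudes for the canonical half lattice; the real
    field is h(r) = sum_half 2 Re[h_q exp(i q.r)] (Hermitian completion).
    """

    def __init__(self, L: float, nvecs_half: np.ndarray, coeffs: np.ndarray):
        self.L = float(L)
        self.nvecs_half = nvecs_half
        self.coeffs = coeffs
        self.q_half = 2 * np.pi / self.L * nvecs_half.astype(float)

    def modes(self) -> tuple[np.ndarray, np.ndarray]:
        """Full Hermitian mode set (nvecs, amplitudes)."""
        nvecs = np.concatenate([self.nvecs_half, -self.nvecs_half])
        amps = np.concatenate([self.coeffs, np.conj(self.coeffs)])
        return nvecs, amps

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        phase = np.asarray(xy, dtype=float) @ self.q_half.T
        return 2.0 * np.real(np.exp(1j * phase) @ self.coeffs)

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        phase = np.asarray(xy, dtype=float) @ self.q_half.T
        e = np.exp(1j * phase)
        hx = 2.0 * np.real(e @ (1j * self.q_half[:, 0] * self.coeffs))
        hy = 2.0 * np.real(e @ (1j * self.q_half[:, 1] * self.coeffs))
        return np.column_stack([hx, hy])

    def spatial_variance(self) -> float:
        """Realized variance of h over the box: sum_full |h_q|^2."""
        return float(2.0 * np.sum(np.abs(self.coeffs) ** 2))


def sample_height_field(params: SynthParams, rng: np.random.Generator) -> HeightField:
    """Draw one equilibrium realization of the undulation field."""
    nvecs = _half_modes(params.n_max)
    var = mode_variances(params, nvecs)
    re = rng.normal(scale=np.sqrt(var / 2.0))
    im = rng.normal(scale=np.sqrt(var / 2.0))
    return HeightField(params.L, nvecs, re + 1j * im)


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _normalize_rows(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _mean_inverse_sq_pair_distance(xy: np.ndarray, L: float, cutoff: float) -> float:
    disp = xy[None, :, :] - xy[:, None, :]
    disp -= L * np.round(disp / L)
    d2 = np.sum(disp ** 2, axis=-1)
    iu, ju = np.triu_indices(len(xy), k=1)
    vals = d2[iu, ju]
    vals = vals[vals <= cutoff ** 2]
    return float(np.mean(1.0 / vals))


def generate_trajectory(
    params: SynthParams, path=None
) -> tuple[Trajectory, dict]:
    """Generate a synthetic two-bead-per-lipid membrane trajectory.

    Per frame (independent equilibrium samples): lipids sit on jittered
    lateral lattices (one per leaflet, half-spacing offset), head
    z = +-d/2 + h(x, y) + N(0, a) around the box mid-plane, and one
    tail_terminal bead is placed opposite the tilt director. Lateral
    positions follow a shared-per-lipid 2D Gaussian walk with step variance
    2 D dt per axis. Deterministic given (params.seed).

    Returns (trajectory, ground_truth). If ``path`` is given the internal
    HDF5 file plus a JSON ground-truth sidecar are written.
    """
    rng = np.random.default_rng(params.seed)
    n_side = math.isqrt(params.n_lipids)
    if n_side * n_side != params.n_lipids:
        raise ParameterError(
            f"lattice cannot host {params.n_lipids} lipids per leaflet "
            "(must be a perfect square)"
        )
    spacing = params.L / n_side
    F, M = params.n_frames, params.n_lipids
    Lz = params.lz_factor * params.d
    z_mid = Lz / 2.0

    grid = (np.arange(n_side) + 0.5) * spacing
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    base = np.empty((2 * M, 2))
    base[:M] = lattice
    base[M:] = np.mod(lattice + spacing / 2.0, params.L)
    base += rng.uniform(-0.25 * spacing, 0.25 * spacing, size=(2 * M, 2))

    # lateral Gaussian walk, shared by all beads of a lipid
    if params.D > 0:
        steps = rng.normal(
            scale=np.sqrt(2.0 * params.D * params.dt), size=(F - 1, 2 * M, 2)
        )
        walk = np.concatenate(
            [np.zeros((1, 2 * M, 2)), np.cumsum(steps, axis=0)], axis=0
        )
        xy = np.mod(base[None, :, :] + walk, params.L)
    else:
        xy = np.broadcast_to(base, (F, 2 * M, 2)).copy()

    nvecs_half = _half_modes(params.n_max)
    var = mode_variances(params, nvecs_half)
    coeffs = (
        rng.normal(scale=np.sqrt(var / 2.0), size=(F, len(nvecs_half)))
        + 1j * rng.normal(scale=np.sqrt(var / 2.0), size=(F, len(nvecs_half)))
    )
    q_half = 2 * np.pi / params.L * nvecs_half.astype(float)

    z_noise = rng.normal(scale=np.sqrt(params.a), size=(F, 2 * M))
    if params.splay_mode == "direct":
        # Var(S_t) for director noise delta: Var = 2 sigma_t^2 E[1/h^2] over
        # neighbor pairs; calibrate E[1/h^2] on the realized frame-0 lattice
        # (1.2 nm pair cutoff, the estimator default)
        target_var = 1.0 / (params.K_c * params.A_l)   # Var(S_t), nm^-2
        inv_h2 = _mean_inverse_sq_pair_distance(base[:M], params.L, cutoff=1.2)
        tilt_sd = np.sqrt(target_var / (2.0 * inv_h2))
    else:
        tilt_sd = params.tilt_sd
    tilt = rng.normal(scale=tilt_sd, size=(F, 2 * M, 2))

    leaflet_sign = np.concatenate([np.ones(M), -np.ones(M)])
    positions = np.empty((F, 4 * M, 3))
    static_xy = params.D == 0
    if static_xy:
        phase0 = xy[0] @ q_half.T
        E0 = np.exp(1j * phase0)
    for f in range(F):
        if static_xy:
            e = E0
        else:
            e = np.exp(1j * (xy[f] @ q_half.T))
        h = 2.0 * np.real(e @ coeffs[f])
        hx = 2.0 * np.real(e @ (1j * q_half[:, 0] * coeffs[f]))
        hy = 2.0 * np.real(e @ (1j * q_half[:, 1] * coeffs[f]))
        head_z = z_mid + leaflet_sign * params.d / 2.0 + h + z_noise[f]
        # outward surface normal per leaflet, then lateral tilt noise
        normals = np.column_stack([-hx, -hy, np.ones(2 * M)])
        normals *= leaflet_sign[:, None]
        normals = _normalize_rows(normals)
        directors = normals.copy()
        directors[:, :2] += tilt[f]
        directors = _normalize_rows(directors)
        heads = np.column_stack([xy[f], head_z])
        tails = heads - params.tail_length * directors
        tails[:, :2] = np.mod(tails[:, :2], params.L)
        positions[f, 0::2, :] = heads
        positions[f, 1::2, :] = tails

    lipid_id = np.repeat(np.arange(2 * M), 2)
    role = np.tile(np.array(["head", "tail_terminal"], dtype=object), 2 * M)
    species_cycle = [params.species[i % len(params.species)] for i in range(2 * M)]
    species = np.repeat(np.array(species_cycle, dtype=object), 2)
    meta = BeadTable(lipid_id, species, role)

    box = np.tile([params.L, params.L, Lz], (F, 1))
    times = np.arange(F) * params.dt

    var_h_theory = float(2.0 * np.sum(var))
    ground_truth = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "kappa_kBT": params.kappa,
        "tension_kBT_per_nm2": params.tension,
        "d_nm": params.d,
        "a_nm2": params.a,
        "D_nm2_per_ps": params.D,
        "tilt_sd": float(tilt_sd),
        "var_h_theory_nm2": var_h_theory,
        "leaflet_labels": ["top"] * M + ["bottom"] * M,
        "seed": params.seed,
    }
    traj = Trajectory(
        positions, box, times, meta,
        temperature=params.temperature,
        provenance={"kind": "synthetic", "ground_truth": {
            k: v for k, v in ground_truth.items() if k != "leaflet_labels"
        }},
    )
    if path is not None:
        path = Path(path)
        write_h5(traj, path)
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(ground_truth, indent=2))
    return traj, ground_truth


# ---------------------------------------------------------------------------
# direct splay sampling
# ---------------------------------------------------------------------------

def generate_splay_samples(
    K_c: float, A_l: float, temperature: float = 300.0, n: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """I.i.d. splay draws from N(0, k_B T / (K_c A_l)) (k_B T = 1; nm^-1)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if K_c <= 0:
        raise ConfigurationError("K_c must be positive")
    if A_l <= 0:
        raise ConfigurationError("A_l must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.normal(scale=np.sqrt(1.0 / (K_c * A_l)), size=n)
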