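"""Real-space splay-fluctuation bending-modulus estimator.

Per-lipid tilt directors and local interface normals are combined into
pairwise splay values S_t; the splay distribution is Boltzmann-inverted,
-(2 k_B T / A_l) ln P(S_t) = K_c S_t^2 + const, and the quadratic
coefficient gives the monolayer splay modulus K_c. Doubling it yields the
bilayer bending modulus. Multi-component systems combine per-species-pair
moduli with a pair-count-weighted harmonic mean.

Reduced units: k_B T = 1; K_c in k_B T, splay in nm^-1, A_l in nm^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateLipidError, FitError
from .geometry_props import apl_series
from .spectral_q4 import ModulusEstimate
from .trajectory_model import (
    BeadFrame,
    LeafletAssignment,
    Trajectory,
    minimum_image,
)


# ---------------------------------------------------------------------------
# directors
# ---------------------------------------------------------------------------

@dataclass
class LipidDirector:
    """Tilt director and local interface normal of one lipid."""

    lipid_id: int
    p: np.ndarray        # lateral position (2,), nm
    n: np.ndarray        # unit tilt director (3,)
    normal: np.ndarray   # unit local interface normal (3,)
    leaflet: str

    def __post_init__(self):
        if abs(np.linalg.norm(self.n) - 1.0) > 1e-10:
            raise DegenerateLipidError("director must be a unit vector")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-10:
            raise DegenerateLipidError("normal must be a unit vector")
        if float(np.dot(self.n, self.normal)) <= 0:
            raise DegenerateLipidError("orientation convention violated (n.N <= 0)")


@dataclass
class DirectorField:
    """Array-of-struct view of all lipid directors in a frame."""

    lipid_ids: np.ndarray    # (M,)
    p: np.ndarray            # (M, 2) lateral head positions
    n: np.ndarray            # (M, 3) unit tilt directors
    normals: np.ndarray      # (M, 3) unit local normals
    leaflet: np.ndarray      # (M,) 'top'/'bottom'
    species: np.ndarray      # (M,)
    box: np.ndarray          # (3,)

    def director(self, i: int) -> LipidDirector:
        return LipidDirector(
            int(self.lipid_ids[i]), self.p[i], self.n[i], self.normals[i],
            str(self.leaflet[i]),
        )


def compute_directors(
    frame: BeadFrame, assignment: LeafletAssignment
) -> tuple[np.ndarray, np.ndarray]:
    """Unit tilt directors per lipid (lipid_ids order).

    n = normalize(head - centroid of tail_terminal beads), with tail-bead
    displacements taken minimum-image relative to the head; the director is
    flipped if needed so it points away from the bilayer midplane (n_z > 0
    on the top leaflet, n_z < 0 on the bottom).

    Returns (p, n): lateral head positions (M, 2) and directors (M, 3).
    """
    meta = frame.meta
    heads = frame.head_positions()
    lipid_ids = meta.lipid_ids
    tt_idx = np.flatnonzero(meta.role == "tail_terminal")
    # map each tail bead to its lipid's position in lipid_ids order
    lipid_pos = np.searchsorted(lipid_ids, meta.lipid_id[tt_idx])
    disp = minimum_image(frame.positions[tt_idx] - heads[lipid_pos], frame.box)
    sums = np.zeros((len(lipid_ids), 3))
    np.add.at(sums, lipid_pos, disp)
    counts = np.bincount(lipid_pos, minlength=len(lipid_ids))
    n_vec = -sums / counts[:, None]          # head - tail centroid
    norms = np.linalg.norm(n_vec, axis=1)
    if np.any(norms < 1e-12):
        bad = lipid_ids[norms < 1e-12][0]
        raise DegenerateLipidError(f"lipid {bad} has a zero-length director")
    n_vec /= norms[:, None]
    signs = assignment.signs()
    flip = n_vec[:, 2] * signs < 0
    n_vec[flip] *= -1.0
    return heads[:, :2], n_vec


def local_normals(
    frame: BeadFrame,
    assignment: LeafletAssignment,
    patch_radius: float = 1.5,
) -> np.ndarray:
    """Local interface normal per lipid from a least-squares plane fit.

    The plane is fit (via the smallest principal axis) to same-leaflet head
    beads within ``patch_radius`` of each head (lateral minimum image);
    normals are oriented away from the midplane. Lipids with fewer than 3
    neighbors fall back to the global leaflet normal with a warning.
    """
    heads = frame.head_positions()
    M = len(heads)
    normals = np.empty((M, 3))
    signs = assignment.signs()
    fallback = 0
    for mask in (assignment.top_mask, assignment.bottom_mask):
        idx = np.flatnonzero(mask)
        pts = heads[idx]
        # pairwise minimum-image displacements within the leaflet
        disp = pts[None, :, :] - pts[:, None, :]
        disp[..., :2] = minimum_image(disp[..., :2], frame.box[:2])
        lat2 = np.sum(disp[..., :2] ** 2, axis=-1)
        near = lat2 <= patch_radius ** 2          # includes self
        counts = near.sum(axis=1)
        w = near.astype(float)
        mean = np.einsum("ij,ijk->ik", w, disp) / counts[:, None]
        centered = disp - mean[:, None, :]
        cov = np.einsum("ij,ija,ijb->iab", w, centered, centered)
        good = counts >= 3
        if np.any(good):
            _, vecs = np.linalg.eigh(cov[good])
            nrm = vecs[:, :, 0]                    # smallest-eigenvalue axis
            sgn = signs[idx[good]]
            flip = nrm[:, 2] * sgn < 0
            nrm[flip] *= -1.0
            normals[idx[good]] = nrm
        if np.any(~good):
            fallback += int((~good).sum())
            normals[idx[~good]] = np.array([0.0, 0.0, 1.0])
            normals[idx[~good], 2] = signs[idx[~good]]
    if fallback:
        warnings.warn(
            f"{fallback} lipid(s) had <3 neighbors within {patch_radius} nm; "
            "global leaflet normal used",
            RuntimeWarning, stacklevel=2,
        )
    return normals


def director_field(
    frame: BeadFrame,
    assignment: LeafletAssignment,
    patch_radius: float = 1.5,
) -> DirectorField:
    p, n = compute_directors(frame, assignment)
    normals = local_normals(frame, assignment, patch_radius)
    return DirectorField(
        lipid_ids=frame.meta.lipid_ids, p=p, n=n, normals=normals,
        leaflet=assignment.labels, species=frame.meta.species_of_lipids(),
        box=frame.box,
    )


# ---------------------------------------------------------------------------
# neighbor pairs and splay
# ---------------------------------------------------------------------------

def neighbor_pairs(
    frame: BeadFrame,
    assignment: LeafletAssignment,
    cutoff: float = 1.2,
) -> np.ndarray:
    """Unordered same-leaflet head-bead pairs within ``cutoff`` (lateral
    minimum image). Returns an (n_pairs, 2) array of lipid indices
    (positions in lipid_ids order), each pair listed once.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    heads = frame.head_positions()[:, :2]
    pairs = []
    for mask in (assignment.top_mask, assignment.bottom_mask):
        idx = np.flatnonzero(mask)
        pts = heads[idx]
        disp = minimum_image(pts[None, :, :] - pts[:, None, :], frame.box[:2])
        d2 = np.sum(disp ** 2, axis=-1)
        iu, ju = np.triu_indices(len(idx), k=1)
        keep = d2[iu, ju] <= cutoff ** 2
        pairs.append(np.column_stack([idx[iu[keep]], idx[ju[keep]]]))
    return np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=int)


def pair_splay(
    a: LipidDirector, b: LipidDirector, box=None, convention: str = "difference"
) -> float:
    """Two-point splay of a lipid pair (nm^-1).

    Default 'difference' convention, consistent with the (grad n - grad N)
    free energy: S_t = [(n_b - n_a) . e1 - (N_b - N_a) . e1] / h with e1 the
    unit lateral separation and h the lateral distance. The literal printed
    'sum' assembly [(n_b - n_a) + (N_b - N_a)] . e1 / h is selectable.
    Swapping the two lipids leaves S_t unchanged.
    """
    sep = np.asarray(b.p, dtype=float) - np.asarray(a.p, dtype=float)
    if box is not None:
        sep = minimum_image(sep, np.asarray(box)[:2])
    h = float(np.linalg.norm(sep))
    if h < 1e-6:
        raise DegenerateLipidError("coincident pair (lateral separation ~ 0)")
    e1 = np.array([sep[0], sep[1], 0.0]) / h
    dn = float((b.n - a.n) @ e1)
    dN = float((b.normal - a.normal) @ e1)
    if convention == "difference":
        return (dn - dN) / h
    if convention == "sum":
        return (dn + dN) / h
    raise ConfigurationError(f"unknown splay convention {convention!r}")


def splay_samples(
    field: DirectorField, pairs: np.ndarray, convention: str = "difference"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair splay; returns (S_t, species_pair_keys)."""
    if convention not in ("difference", "sum"):
        raise ConfigurationError(f"unknown splay convention {convention!r}")
    ia, ib = pairs[:, 0], pairs[:, 1]
    sep = minimum_image(field.p[ib] - field.p[ia], field.box[:2])
    h = np.linalg.norm(sep, axis=1)
    if np.any(h < 1e-6):
        raise DegenerateLipidError("coincident pair (lateral separation ~ 0)")
    e1 = sep / h[:, None]
    dn = np.einsum("ij,ij->i", (field.n[ib] - field.n[ia])[:, :2], e1)
    dN = np.einsum("ij,ij->i", (field.normals[ib] - field.normals[ia])[:, :2], e1)
    s = (dn - dN) / h if convention == "difference" else (dn + dN) / h
    keys = np.array(
        ["|".join(sorted((str(field.species[i]), str(field.species[j]))))
         for i, j in pairs],
        dtype=object,
    )
    return s, keys


# ---------------------------------------------------------------------------
# distribution and Boltzmann inversion
# ---------------------------------------------------------------------------

@dataclass
class SplayDistribution:
    """Histogrammed splay samples and the Boltzmann-inverted energy curve."""

    samples: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    P: np.ndarray            # normalized density: sum(P * bin_width) = 1
    bin_width: float
    A_l: float               # nm^2
    temperature: float       # K
    species_pair: str = "all"

    @property
    def energy(self) -> np.ndarray:
        """-(2 k_B T / A_l) ln P at occupied bins (k_B T = 1), else nan."""
        with np.errstate(divide="ignore"):
            return np.where(self.P > 0, -(2.0 / self.A_l) * np.log(self.P), np.nan)


def splay_distribution(
    samples: np.ndarray,
    A_l: float,
    temperature: float = 300.0,
    n_bins: int = 101,
    species_pair: str = "all",
) -> SplayDistribution:
    """Histogram P(S_t) over mean +- 4 SD with ``n_bins`` bins."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise FitError("empty splay sample set")
    if A_l <= 0:
        raise ConfigurationError("A_l must be positive")
    sd = samples.std()
    if sd == 0:
        raise FitError("degenerate splay distribution (zero variance)")
    lo, hi = samples.mean() - 4 * sd, samples.mean() + 4 * sd
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    width = edges[1] - edges[0]
    P = counts / (counts.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SplayDistribution(
        samples=samples, bin_centers=centers, counts=counts, P=P,
        bin_width=float(width), A_l=float(A_l), temperature=temperature,
        species_pair=species_pair,
    )


def fit_splay_modulus(dist: SplayDistribution, min_count: int = 10) -> ModulusEstimate:
    """Boltzmann inversion of P(S_t).

    Quadratic least squares of -(2 k_B T / A_l) ln P against S_t with a free
    intercept (absorbing the normalization constant); the quadratic
    coefficient is the monolayer splay modulus K_c and the reported bilayer
    bending modulus is exactly 2 K_c.
    """
    keep = dist.counts >= min_count
    if int(keep.sum()) < 5:
        raise FitError(
            f"only {int(keep.sum())} bins with >= {min_count} counts (>=5 required)"
        )
    s = dist.bin_centers[keep]
    y = dist.energy[keep]
    X = np.column_stack([np.ones_like(s), s, s ** 2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    K_c = float(coef[2])
    if K_c <= 0:
        raise FitError(f"non-positive curvature in splay energy fit (K_c={K_c:.4g})")
    dof = max(len(s) - 3, 1)
    sigma2 = float(np.sum((y - X @ coef) ** 2)) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[2, 2]))
    return ModulusEstimate(
        method="rsf", kappa=monolayer_to_bilayer(K_c), kappa_se=2.0 * se,
        window={"n_bins": len(s), "min_count": min_count},
        temperature=dist.temperature,
        extras={
            "K_c_monolayer_kBT": K_c, "K_c_se_kBT": se,
            "A_l_nm2": dist.A_l, "n_samples": int(dist.samples.size),
            "species_pair": dist.species_pair,
        },
    )


def monolayer_to_bilayer(K_c: float) -> float:
    """Bilayer bending modulus from the monolayer splay modulus (factor 2)."""
    return 2.0 * K_c


# ---------------------------------------------------------------------------
# multi-component combination
# ---------------------------------------------------------------------------

@dataclass
class PairModuli:
    """Per species-pair pair counts (phi) and splay moduli (chi, k_B T)."""

    phi: dict
    chi: dict

    def __post_init__(self):
        if set(self.phi) != set(self.chi):
            raise ConfigurationError("phi and chi must cover the same pairs")
        if any(c <= 0 for c in self.chi.values()):
            raise ConfigurationError("all chi must be positive")
        if self.phi_total <= 0:
            raise ConfigurationError("phi_total must be positive")

    @property
    def phi_total(self) -> float:
        return float(sum(self.phi.values()))


def combine_pair_moduli(pm: PairModuli) -> float:
    """Pair-count-weighted harmonic combination:
    1/K_c = (1/phi_total) sum_ij phi_ij / chi_ij."""
    inv = sum(pm.phi[k] / pm.chi[k] for k in pm.phi) / pm.phi_total
    return 1.0 / inv


# ---------------------------------------------------------------------------
# end-to-end estimator
# ---------------------------------------------------------------------------

def rsf_modulus(
    traj: Trajectory,
    assignment: LeafletAssignment,
    A_l: float | None = None,
    cutoff: float = 1.2,
    patch_radius: float = 1.5,
    convention: str = "difference",
    n_bins: int = 101,
    per_species: bool | None = None,
) -> ModulusEstimate:
    """Full real-space-fluctuation pipeline for one trajectory.

    Collects pair splays over all frames, builds the distribution with
    A_l from :func:`~memflex.geometry_props.area_per_lipid` (unless given),
    and Boltzmann-inverts it. With more than one species (or
    ``per_species=True``), per-pair distributions are fit separately and
    combined with :func:`combine_pair_moduli`.
    """
    if A_l is None:
        A_l = float(apl_series(traj, assignment).mean())
    all_s: list[np.ndarray] = []
    all_keys: list[np.ndarray] = []
    for frame in traj.frames():
        field_ = director_field(frame, assignment, patch_radius)
        pairs = neighbor_pairs(frame, assignment, cutoff)
        if len(pairs) == 0:
            continue
        s, keys = splay_samples(field_, pairs, convention)
        all_s.append(s)
        all_keys.append(keys)
    if not all_s:
        raise FitError("no neighbor pairs found; increase the cutoff")
    samples = np.concatenate(all_s)
    keys = np.concatenate(all_keys)
    unique_keys = np.unique(keys)
    if per_species is None:
        per_species = len(unique_keys) > 1

    if not per_species:
        dist = splay_distribution(samples, A_l, traj.temperature, n_bins)
        est = fit_splay_modulus(dist)
    else:
        phi, chi, per_pair = {}, {}, {}
        for k in unique_keys:
            sub = samples[keys == k]
            dist = splay_distribution(sub, A_l, traj.temperature, n_bins,
                                      species_pair=str(k))
            sub_est = fit_splay_modulus(dist)
            phi[str(k)] = int(sub.size)
            chi[str(k)] = sub_est.extras["K_c_monolayer_kBT"]
            per_pair[str(k)] = sub_est.to_dict()
        K_c = combine_pair_moduli(PairModuli(phi, chi))
        est = ModulusEstimate(
            method="rsf", kappa=2.0 * K_c, kappa_se=0.0,
            temperature=traj.temperature,
            extras={
                "K_c_monolayer_kBT": K_c, "A_l_nm2": A_l,
                "per_pair": per_pair, "pair_counts": phi,
            },
        )
    est.extras.setdefault("A_l_nm2", A_l)
    est.extras["convention"] = convention
    est.extras["cutoff_nm"] = cutoff
    est.extras["patch_radius_nm"] = patch_radius
    return est
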