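"""Core data model for bead trajectories.

Holds the in-memory representation of coarse-grained membrane frames
(positions in nm, box in nm, time in ps), readers for GRO/XTC/TRR via
MDAnalysis and for the internal HDF5/CSV dialects, leaflet assignment,
and lateral center-of-mass motion removal.

Internal units throughout the package: nm, ps, K.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateBilayerError,
    EmptyInputError,
    MemflexError,
    NonSquareBoxError,
)

ROLES = ("head", "tail", "tail_terminal", "other")

#: Boltzmann constant, J/K (2019 SI definition).
KB = 1.380649e-23


# ---------------------------------------------------------------------------
# bead metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadTable:
    """Per-bead metadata, constant across frames.

    Attributes
    ----------
    lipid_id : (N,) int array
        Integer lipid identifier for every bead.
    species : (N,) str array
        Species tag (e.g. residue name) per bead.
    role : (N,) str array
        One of :data:`ROLES`.
    """

    lipid_id: np.ndarray
    species: np.ndarray
    role: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lipid_id", np.asarray(self.lipid_id, dtype=np.int64))
        object.__setattr__(self, "species", np.asarray(self.species, dtype=object))
        object.__setattr__(self, "role", np.asarray(self.role, dtype=object))
        n = len(self.lipid_id)
        if len(self.species) != n or len(self.role) != n:
            raise ConfigurationError("bead metadata arrays must have equal length")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise ConfigurationError(f"unknown bead roles: {sorted(bad)}")
        for lid in np.unique(self.lipid_id):
            roles = self.role[self.lipid_id == lid]
            n_head = int(np.sum(roles == "head"))
            n_tt = int(np.sum(roles == "tail_terminal"))
            if n_head != 1:
                raise ConfigurationError(
                    f"lipid {lid} has {n_head} head beads (exactly 1 required)"
                )
            if n_tt < 1:
                raise ConfigurationError(
                    f"lipid {lid} has no tail_terminal bead"
                )

    @property
    def n_beads(self) -> int:
        return len(self.lipid_id)

    @property
    def lipid_ids(self) -> np.ndarray:
        """Sorted unique lipid identifiers."""
        return np.unique(self.lipid_id)

    @property
    def head_index(self) -> np.ndarray:
        """Bead index of the head bead for every lipid in ``lipid_ids`` order."""
        idx = np.flatnonzero(self.role == "head")
        order = np.argsort(self.lipid_id[idx], kind="stable")
        return idx[order]

    def species_of_lipids(self) -> np.ndarray:
        """Species tag per lipid in ``lipid_ids`` order."""
        return self.species[self.head_index]


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    return np.mod(positions, np.asarray(box)[..., None, :])


def minimum_image(disp: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Works on the trailing axis; ``box`` gives the periodic lengths for the
    components present in ``disp`` (pass the lateral box for 2D displacements).
    """
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


@dataclass
class BeadFrame:
    """A single frame of bead positions.

    Positions are wrapped into [0, L) on construction.
    """

    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray        # (3,) nm
    time: float            # ps
    meta: BeadTable

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigurationError("positions must have shape (N, 3)")
        if self.positions.shape[0] != self.meta.n_beads:
            raise ConfigurationError("positions/metadata bead count mismatch")
        if np.any(self.box <= 0):
            raise ConfigurationError("box lengths must be positive")
        self.positions = np.mod(self.positions, self.box)

    @property
    def l_cell(self) -> float:
        """Lateral cell length; requires a square cell."""
        require_square_box(self.box)
        return float(self.box[0])

    def head_positions(self) -> np.ndarray:
        """Head-bead positions in lipid_ids order, shape (n_lipids, 3)."""
        return self.positions[self.meta.head_index]


def require_square_box(box: np.ndarray, rtol: float = 1e-9) -> None:
    if not np.isclose(box[0], box[1], rtol=rtol):
        raise NonSquareBoxError(
            f"square lateral cell required, got L_x={box[0]!r}, L_y={box[1]!r}"
        )


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered sequence of frames with shared bead metadata.

    ``positions`` has shape (F, N, 3); ``box`` (F, 3); ``times`` (F,).
    """

    positions: np.ndarray
    box: np.ndarray
    times: np.ndarray
    meta: BeadTable
    temperature: float = 300.0
    provenance: dict = field(default_factory=lambda: {"kind": "real"})
    com_removed: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ConfigurationError("positions must have shape (F, N, 3)")
        if self.positions.shape[0] == 0:
            raise EmptyInputError("trajectory has no frames")
        if self.box.shape != (self.positions.shape[0], 3):
            raise ConfigurationError("box must have shape (F, 3)")
        if self.times.shape != (self.positions.shape[0],):
            raise ConfigurationError("times must have shape (F,)")
        if self.positions.shape[1] != self.meta.n_beads:
            raise ConfigurationError("positions/metadata bead count mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("frame times must be strictly increasing")
        self.positions = np.mod(self.positions, self.box[:, None, :])

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Spacing between stored frames (ps); 0 for single-frame input."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> BeadFrame:
        return BeadFrame(self.positions[i], self.box[i], float(self.times[i]), self.meta)

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def slice(self, start: int = 0, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory over frames [start, stop)."""
        sl = slice(start, stop)
        return Trajectory(
            self.positions[sl], self.box[sl], self.times[sl], self.meta,
            temperature=self.temperature, provenance=dict(self.provenance),
            com_removed=self.com_removed,
        )

    def head_z(self) -> np.ndarray:
        """Head-bead z coordinates, shape (F, n_lipids), lipid_ids order."""
        return self.positions[:, self.meta.head_index, 2]

    def head_xy(self) -> np.ndarray:
        """Head-bead lateral coordinates, shape (F, n_lipids, 2)."""
        return self.positions[:, self.meta.head_index, :2]


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafletAssignment:
    """Per-lipid top/bottom label, fixed for the whole trajectory.

    ``labels`` is aligned with ``lipid_ids`` (sorted). The assignment is
    computed from a single (by convention, the first) frame; CG head beads
    essentially never flip leaflets, and per-frame reassignment would
    corrupt interleaflet sums downstream.
    """

    lipid_ids: np.ndarray
    labels: np.ndarray          # 'top' / 'bottom'
    midplane: float             # nm, frame used for the assignment
    head_selector: str = "head"

    def __post_init__(self):
        n_top = int(np.sum(self.labels == "top"))
        n_bot = int(np.sum(self.labels == "bottom"))
        if n_top == 0 or n_bot == 0:
            raise DegenerateBilayerError(
                f"degenerate bilayer: {n_top} top / {n_bot} bottom lipids"
            )
        if n_top + n_bot != len(self.lipid_ids):
            raise ConfigurationError("labels must cover every lipid exactly once")

    @property
    def top_mask(self) -> np.ndarray:
        return self.labels == "top"

    @property
    def bottom_mask(self) -> np.ndarray:
        return self.labels == "bottom"

    @property
    def n_top(self) -> int:
        return int(np.sum(self.top_mask))

    @property
    def n_bottom(self) -> int:
        return int(np.sum(self.bottom_mask))

    def signs(self) -> np.ndarray:
        """+1 for top lipids, -1 for bottom, lipid_ids order."""
        return np.where(self.top_mask, 1.0, -1.0)


def assign_leaflets(frame: BeadFrame, head_selector: str = "head") -> LeafletAssignment:
    """Assign each lipid to the top or bottom leaflet.

    The midplane is the mean z of all head beads; a lipid is *top* iff its
    head z exceeds the midplane.
    """
    if head_selector not in ROLES:
        raise ConfigurationError(f"unknown head selector role: {head_selector!r}")
    lipid_ids = frame.meta.lipid_ids
    if len(lipid_ids) < 2:
        raise ConfigurationError("leaflet assignment requires at least 2 lipids")
    head_z = frame.positions[frame.meta.head_index, 2]
    midplane = float(np.mean(head_z))
    labels = np.where(head_z > midplane, "top", "bottom").astype(object)
    return LeafletAssignment(lipid_ids, labels, midplane, head_selector)


def assign_leaflets_trajectory(
    traj: Trajectory,
    head_selector: str = "head",
    flip_tolerance: float | None = None,
) -> LeafletAssignment:
    """Assign leaflets on the first frame; warn about apparent flip-flops.

    A warning is emitted if any head bead later crosses the instantaneous
    midplane by more than ``flip_tolerance`` (default d/4, with d estimated
    from the assignment itself). Flip-flop is not modeled.
    """
    assignment = assign_leaflets(traj.frame(0), head_selector)
    head_z = traj.head_z()
    midplane = head_z.mean(axis=1, keepdims=True)
    rel = head_z - midplane
    if flip_tolerance is None:
        d_est = float(
            rel[0, assignment.top_mask].mean() - rel[0, assignment.bottom_mask].mean()
        )
        flip_tolerance = d_est / 4.0
    signs = assignment.signs()
    crossing = rel * signs < -flip_tolerance
    if np.any(crossing):
        n_bad = int(np.any(crossing, axis=0).sum())
        warnings.warn(
            f"{n_bad} lipid(s) crossed the instantaneous midplane by more than "
            f"{flip_tolerance:.3g} nm; fixed first-frame leaflet assignment kept "
            "(flip-flop is not modeled)",
            RuntimeWarning,
            stacklevel=2,
        )
    return assignment


# ---------------------------------------------------------------------------
# center-of-mass motion removal
# ---------------------------------------------------------------------------

def remove_com_motion(traj: Trajectory) -> Trajectory:
    """Remove lateral (x, y) drift of the overall bead centroid.

    The unwrapped centroid displacement relative to the first frame is
    subtracted from every frame, so the per-frame lateral centroid equals
    the first-frame centroid exactly. z is left intact. Idempotent, and
    preserves all pairwise minimum-image lateral distances.
    """
    pos = traj.positions.copy()
    lateral_box = traj.box[:, :2]
    # unwrapped frame-to-frame centroid drift via per-bead minimum-image steps
    steps = np.diff(pos[:, :, :2], axis=0)
    steps = minimum_image(steps, lateral_box[1:, None, :])
    drift = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(steps.mean(axis=1), axis=0)], axis=0
    )
    pos[:, :, :2] -= drift[:, None, :]
    return Trajectory(
        pos, traj.box, traj.times, traj.meta,
        temperature=traj.temperature,
        provenance=dict(traj.provenance),
        com_removed=True,
    )


# ---------------------------------------------------------------------------
# internal HDF5 / CSV dialects
# ---------------------------------------------------------------------------
#
# HDF5 layout:
#   /positions  (F, N, 3) float64, nm
#   /box        (F, 3)    float64, nm
#   /time       (F,)      float64, ps
#   /meta/lipid_id, /meta/species, /meta/role   (N,) arrays
#   attrs: temperature (K), provenance (JSON), com_removed
#
# CSV fallback (tiny fixtures): one long table with columns
#   frame,time,Lx,Ly,Lz,bead,lipid_id,species,role,x,y,z

def write_h5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        # track_times=False keeps output byte-identical for fixed inputs
        fh.create_dataset("positions", data=traj.positions, track_times=False)
        fh.create_dataset("box", data=traj.box, track_times=False)
        fh.create_dataset("time", data=traj.times, track_times=False)
        grp = fh.create_group("meta", track_order=False)
        grp.create_dataset("lipid_id", data=traj.meta.lipid_id, track_times=False)
        str_dt = "S32"
        grp.create_dataset("species", data=traj.meta.species.astype(str_dt),
                           track_times=False)
        grp.create_dataset("role", data=traj.meta.role.astype(str_dt),
                           track_times=False)
        fh.attrs["temperature"] = traj.temperature
        fh.attrs["provenance"] = json.dumps(traj.provenance)
        fh.attrs["com_removed"] = traj.com_removed
        fh.attrs["format_version"] = 1


def read_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        meta = BeadTable(
            lipid_id=fh["meta/lipid_id"][...],
            species=np.array([s.decode() for s in fh["meta/species"][...]], dtype=object),
            role=np.array([s.decode() for s in fh["meta/role"][...]], dtype=object),
        )
        traj = Trajectory(
            positions=fh["positions"][...],
            box=fh["box"][...],
            times=fh["time"][...],
            meta=meta,
            temperature=float(fh.attrs["temperature"]),
            provenance=json.loads(fh.attrs["provenance"]),
            com_removed=bool(fh.attrs["com_removed"]),
        )
    return traj


def write_csv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("frame,time,Lx,Ly,Lz,bead,lipid_id,species,role,x,y,z\n")
        for f in range(traj.n_frames):
            Lx, Ly, Lz = (float(v) for v in traj.box[f])
            t = float(traj.times[f])
            for b in range(traj.n_beads):
                x, y, z = (float(v) for v in traj.positions[f, b])
                fh.write(
                    f"{f},{t!r},{Lx!r},{Ly!r},{Lz!r},{b},"
                    f"{traj.meta.lipid_id[b]},{traj.meta.species[b]},"
                    f"{traj.meta.role[b]},{x!r},{y!r},{z!r}\n"
                )


def read_csv(path, temperature: float = 300.0) -> Trajectory:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        for line in fh:
            rows.append(line.strip().split(","))
    if not rows:
        raise EmptyInputError(f"no frames in {path}")
    col = {name: i for i, name in enumerate(header)}
    frames = sorted({int(r[col["frame"]]) for r in rows})
    beads = sorted({int(r[col["bead"]]) for r in rows})
    F, N = len(frames), len(beads)
    positions = np.zeros((F, N, 3))
    box = np.zeros((F, 3))
    times = np.zeros(F)
    lipid_id = np.zeros(N, dtype=np.int64)
    species = np.empty(N, dtype=object)
    role = np.empty(N, dtype=object)
    for r in rows:
        f, b = int(r[col["frame"]]), int(r[col["bead"]])
        positions[f, b] = [float(r[col[a]]) for a in "xyz"]
        box[f] = [float(r[col[a]]) for a in ("Lx", "Ly", "Lz")]
        times[f] = float(r[col["time"]])
        lipid_id[b] = int(r[col["lipid_id"]])
        species[b] = r[col["species"]]
        role[b] = r[col["role"]]
    meta = BeadTable(lipid_id, species, role)
    return Trajectory(positions, box, times, meta, temperature=temperature)


# ---------------------------------------------------------------------------
# standard-format reader (GRO + XTC/TRR via MDAnalysis)
# ---------------------------------------------------------------------------

def _roles_from_selectors(resname: str, atom_names: Sequence[str],
                          selectors: Mapping[str, Mapping[str, Sequence[str]]]):
    if resname not in selectors:
        raise ConfigurationError(
            f"unknown species tag {resname!r}: no selector configured"
        )
    sel = selectors[resname]
    heads = set(sel.get("head", ()))
    tails = set(sel.get("tail_terminal", ()))
    roles = []
    for name in atom_names:
        if name in heads:
            roles.append("head")
        elif name in tails:
            roles.append("tail_terminal")
        else:
            roles.append("other")
    return roles


def read_trajectory(
    coordinate_path,
    trajectory_path=None,
    selectors: Mapping | None = None,
    temperature: float = 300.0,
) -> Trajectory:
    """Read a trajectory from disk.

    Dispatches on suffix: ``.h5``/``.hdf5`` for the internal HDF5 dialect,
    ``.csv`` for the CSV fallback, ``.gro`` for a GRO coordinate file
    optionally paired with an XTC/TRR trajectory. For GRO input,
    ``selectors`` must map species (residue name) to head / tail_terminal
    bead names.
    """
    coordinate_path = Path(coordinate_path)
    if not coordinate_path.exists():
        raise ConfigurationError(f"coordinate file not found: {coordinate_path}")
    suffix = coordinate_path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return read_h5(coordinate_path)
    if suffix == ".csv":
        return read_csv(coordinate_path, temperature=temperature)
    if suffix != ".gro":
        raise ConfigurationError(f"unsupported coordinate format: {suffix!r}")

    if selectors is None:
        raise ConfigurationError("GRO input requires species selectors")
    import MDAnalysis as mda

    args = [str(coordinate_path)]
    if trajectory_path is not None:
        tp = Path(trajectory_path)
        if not tp.exists():
            raise ConfigurationError(f"trajectory file not found: {tp}")
        args.append(str(tp))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*args)

    lipid_id = np.zeros(len(u.atoms), dtype=np.int64)
    species = np.empty(len(u.atoms), dtype=object)
    role = np.empty(len(u.atoms), dtype=object)
    for res in u.residues:
        idx = res.atoms.ix
        lipid_id[idx] = res.resindex
        species[idx] = res.resname
        role[idx] = _roles_from_selectors(res.resname, list(res.atoms.names), selectors)
    meta = BeadTable(lipid_id, species, role)

    positions, boxes, times = [], [], []
    for ts in u.trajectory:
        positions.append(ts.positions / 10.0)  # Angstrom -> nm
        boxes.append(ts.dimensions[:3] / 10.0)
        times.append(ts.time)
    if not positions:
        raise EmptyInputError(f"no frames in {coordinate_path}")
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.all(np.diff(times) == 0.0):
        times = np.arange(len(times), dtype=float)
    return Trajectory(
        np.asarray(positions), np.asarray(boxes), times, meta,
        temperature=temperature,
        provenance={"kind": "real", "source": str(coordinate_path)},
    )


def write_gro(frame: BeadFrame, path, title: str = "memflex frame") -> None:
    """Write a single frame as a GRO coordinate file (for visual inspection)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{frame.meta.n_beads:d}\n")
        names = {"head": "HD", "tail": "TL", "tail_terminal": "TT", "other": "OT"}
        for b in range(frame.meta.n_beads):
            resid = int(frame.meta.lipid_id[b]) % 100000 + 1
            resname = str(frame.meta.species[b])[:5]
            name = names[str(frame.meta.role[b])]
            x, y, z = frame.positions[b]
            fh.write(f"{resid:5d}{resname:<5s}{name:>5s}{b % 100000 + 1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")
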