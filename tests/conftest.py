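import numpy as np
import pytest

from memflex.trajectory_model import BeadTable, Trajectory, assign_leaflets_trajectory
from memflex.synthetic_membrane import SynthParams, generate_trajectory


def two_bead_meta(n_lipids, species=None):
    """Metadata for n_lipids lipids of (head, tail_terminal) bead pairs."""
    lipid_id = np.repeat(np.arange(n_lipids), 2)
    role = np.tile(np.array(["head", "tail_terminal"], dtype=object), n_lipids)
    if species is None:
        species = ["LIP"] * n_lipids
    sp = np.repeat(np.array(species, dtype=object), 2)
    return BeadTable(lipid_id, sp, role)


def flat_bilayer_positions(n_per_leaflet, L, d, rng=None, jitter=0.0, z_mid=None):
    """Heads on jittered lattices at z_mid +- d/2, tails 1 nm toward midplane.

    Returns a (4*n, 3) position array; bead order is (head, tail) per lipid,
    top leaflet first.
    """
    if z_mid is None:
        z_mid = 2.5 * d
    n_side = int(round(np.sqrt(n_per_leaflet)))
    assert n_side * n_side == n_per_leaflet
    g = (np.arange(n_side) + 0.5) * (L / n_side)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    lat = np.column_stack([gx.ravel(), gy.ravel()])
    lat2 = np.mod(lat + L / (2 * n_side), L)
    xy = np.concatenate([lat, lat2])
    if jitter and rng is not None:
        xy = np.mod(xy + rng.uniform(-jitter, jitter, xy.shape), L)
    sign = np.concatenate([np.ones(n_per_leaflet), -np.ones(n_per_leaflet)])
    heads = np.column_stack([xy, z_mid + sign * d / 2])
    tails = heads.copy()
    tails[:, 2] -= sign * 1.0
    pos = np.empty((4 * n_per_leaflet, 3))
    pos[0::2] = heads
    pos[1::2] = tails
    return pos


def make_trajectory(positions_per_frame, L, Lz, dt=100.0, temperature=300.0,
                    com_removed=False):
    positions = np.asarray(positions_per_frame, dtype=float)
    F = positions.shape[0]
    n_lipids = positions.shape[1] // 2
    box = np.tile([L, L, Lz], (F, 1))
    return Trajectory(
        positions, box, np.arange(F) * dt, two_bead_meta(n_lipids),
        temperature=temperature, com_removed=com_removed,
    )


@pytest.fixture(scope="session")
def small_membrane():
    """Small static synthetic membrane shared by cheap tests."""
    params = SynthParams(
        L=16.0, n_lipids=64, kappa=30.0, a=0.02, n_frames=30, seed=11
    )
    traj, truth = generate_trajectory(params)
    assignment = assign_leaflets_trajectory(traj)
    return traj, truth, assignment
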