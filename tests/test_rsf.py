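import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memflex.errors import ConfigurationError, DegenerateLipidError, FitError
from memflex.geometry_props import apl_series
from memflex.rsf import (
    LipidDirector,
    PairModuli,
    combine_pair_moduli,
    compute_directors,
    director_field,
    fit_splay_modulus,
    local_normals,
    monolayer_to_bilayer,
    neighbor_pairs,
    pair_splay,
    rsf_modulus,
    splay_distribution,
    splay_samples,
)
from memflex.synthetic_membrane import SynthParams, generate_splay_samples, generate_trajectory
from memflex.trajectory_model import BeadFrame, assign_leaflets, assign_leaflets_trajectory

from conftest import flat_bilayer_positions, two_bead_meta


def simple_frame(head_tail_pairs, L=20.0, Lz=20.0):
    """Frame from a list of (head_xyz, tail_xyz) per lipid."""
    pos = np.array([p for pair in head_tail_pairs for p in pair], dtype=float)
    return BeadFrame(pos, np.array([L, L, Lz]), 0.0,
                     two_bead_meta(len(head_tail_pairs)))


# ---------------------------------------------------------------------------
# directors
# ---------------------------------------------------------------------------

def test_director_vertical_lipids():
    frame = simple_frame([
        ([1, 1, 12], [1, 1, 10]),   # top
        ([2, 2, 12], [2, 2, 10]),
        ([1, 1, 8], [1, 1, 10]),    # bottom (mirrored)
        ([2, 2, 8], [2, 2, 10]),
    ])
    a = assign_leaflets(frame)
    _, n = compute_directors(frame, a)
    np.testing.assert_allclose(n[0], [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(n[2], [0, 0, -1], atol=1e-12)
    # both leaflets satisfy n . N_outward = +1
    normals = local_normals(frame, a, patch_radius=5.0)
    assert np.all(np.einsum("ij,ij->i", n, normals) > 0.99)


def test_director_prescribed_tilt_angle():
    theta = 0.3
    tilt = np.array([np.sin(theta), 0.0, np.cos(theta)])
    head_top = np.array([3.0, 3.0, 12.0])
    frame = simple_frame([
        (head_top, head_top - 2.0 * tilt),
        ([8, 8, 12], [8, 8, 10]),
        ([3, 3, 8], [3, 3, 10]),
        ([8, 8, 8], [8, 8, 10]),
    ])
    a = assign_leaflets(frame)
    _, n = compute_directors(frame, a)
    angle = np.arccos(np.clip(n[0] @ [0, 0, 1], -1, 1))
    assert angle == pytest.approx(theta, abs=1e-10)


def test_director_zero_length_error():
    frame = simple_frame([
        ([1, 1, 12], [1, 1, 12]),
        ([2, 2, 8], [2, 2, 10]),
    ])
    a = assign_leaflets(frame)
    with pytest.raises(DegenerateLipidError):
        compute_directors(frame, a)


# ---------------------------------------------------------------------------
# local normals
# ---------------------------------------------------------------------------

def test_local_normals_flat_leaflet():
    pos = flat_bilayer_positions(16, 12.0, 4.0)
    frame = BeadFrame(pos, np.array([12.0, 12.0, 20.0]), 0.0, two_bead_meta(32))
    a = assign_leaflets(frame)
    N = local_normals(frame, a, patch_radius=4.0)
    np.testing.assert_allclose(N[a.top_mask], [[0, 0, 1]] * 16, atol=1e-10)
    np.testing.assert_allclose(N[a.bottom_mask], [[0, 0, -1]] * 16, atol=1e-10)


def test_local_normals_tilted_plane():
    alpha = 0.25
    rng = np.random.default_rng(40)
    # local cluster, far from periodic images
    xy = np.column_stack([20 + rng.uniform(-1, 1, 12), 20 + rng.uniform(-1, 1, 12)])
    pairs = []
    for x, y in xy:
        z = 30.0 + x * np.tan(alpha)
        pairs.append(([x, y, z + 2], [x, y, z + 1]))
    for x, y in xy:
        z = 30.0 + x * np.tan(alpha)
        pairs.append(([x, y, z - 2], [x, y, z - 1]))
    frame = simple_frame(pairs, L=60.0, Lz=80.0)
    a = assign_leaflets(frame)
    N = local_normals(frame, a, patch_radius=3.0)
    expected = np.array([-np.tan(alpha), 0.0, 1.0])
    expected /= np.linalg.norm(expected)
    for i in np.flatnonzero(a.top_mask):
        np.testing.assert_allclose(N[i], expected, atol=1e-8)


def test_local_normals_isolated_fallback():
    frame = simple_frame([
        ([1, 1, 12], [1, 1, 10]),
        ([30, 30, 12], [30, 30, 10]),
        ([1, 1, 8], [1, 1, 10]),
        ([30, 30, 8], [30, 30, 10]),
    ], L=60.0)
    a = assign_leaflets(frame)
    with pytest.warns(RuntimeWarning, match="neighbors"):
        N = local_normals(frame, a, patch_radius=2.0)
    np.testing.assert_allclose(N[0], [0, 0, 1])


# ---------------------------------------------------------------------------
# neighbor pairs
# ---------------------------------------------------------------------------

def test_neighbor_pairs_simple():
    frame = simple_frame([
        ([1.0, 1.0, 12], [1.0, 1.0, 10]),
        ([1.5, 1.0, 12], [1.5, 1.0, 10]),
        ([1.0, 1.0, 8], [1.0, 1.0, 10]),
        ([5.0, 5.0, 8], [5.0, 5.0, 10]),
    ])
    a = assign_leaflets(frame)
    pairs = neighbor_pairs(frame, a, cutoff=1.2)
    assert len(pairs) == 1
    assert set(pairs[0]) == {0, 1}


def test_neighbor_pairs_lattice_counting():
    # periodic square lattice of spacing 0.8, cutoff 1.0: 4 neighbors each
    n_side = 5
    L = n_side * 0.8
    pos = flat_bilayer_positions(n_side ** 2, L, 4.0)
    frame = BeadFrame(pos, np.array([L, L, 20.0]), 0.0,
                      two_bead_meta(2 * n_side ** 2))
    a = assign_leaflets(frame)
    pairs = neighbor_pairs(frame, a, cutoff=1.0)
    counts = np.zeros(2 * n_side ** 2)
    for i, j in pairs:
        counts[i] += 1
        counts[j] += 1
    assert np.all(counts == 4)


def test_neighbor_pairs_across_boundary():
    frame = simple_frame([
        ([0.2, 1.0, 12], [0.2, 1.0, 10]),
        ([19.8, 1.0, 12], [19.8, 1.0, 10]),
        ([10.0, 1.0, 8], [10.0, 1.0, 10]),
        ([12.0, 1.0, 8], [12.0, 1.0, 10]),
    ])
    a = assign_leaflets(frame)
    pairs = neighbor_pairs(frame, a, cutoff=1.0)
    assert [0, 1] in pairs.tolist()


def test_neighbor_pairs_bad_cutoff():
    frame = simple_frame([([1, 1, 12], [1, 1, 10]), ([1, 1, 8], [1, 1, 10])])
    a = assign_leaflets(frame)
    with pytest.raises(ConfigurationError):
        neighbor_pairs(frame, a, cutoff=0.0)


# ---------------------------------------------------------------------------
# pair splay
# ---------------------------------------------------------------------------

def director(p, n, normal, leaflet="top", lid=0):
    return LipidDirector(lid, np.asarray(p, float), np.asarray(n, float),
                         np.asarray(normal, float), leaflet)


def test_pair_splay_identical_directors():
    z = np.array([0.0, 0.0, 1.0])
    a = director([0, 0], z, z)
    b = director([1, 0], z, z, lid=1)
    assert pair_splay(a, b) == pytest.approx(0.0, abs=1e-15)


def test_pair_splay_symmetric_tilt_trig():
    delta, h = 0.1, 1.0
    z = np.array([0.0, 0.0, 1.0])
    na = np.array([-np.sin(delta), 0.0, np.cos(delta)])
    nb = np.array([np.sin(delta), 0.0, np.cos(delta)])
    a = director([0, 0], na, z)
    b = director([h, 0], nb, z, lid=1)
    assert pair_splay(a, b) == pytest.approx(2 * np.sin(delta) / h, rel=1e-12)
    assert pair_splay(a, b) == pytest.approx(0.19967, abs=5e-5)


def test_pair_splay_swap_invariant():
    rng = np.random.default_rng(41)
    z = np.array([0.0, 0.0, 1.0])

    def rand_dir():
        v = z + np.concatenate([rng.normal(scale=0.2, size=2), [0]])
        return v / np.linalg.norm(v)

    a = director(rng.uniform(0, 5, 2), rand_dir(), rand_dir())
    b = director(rng.uniform(0, 5, 2), rand_dir(), rand_dir(), lid=1)
    assert pair_splay(a, b) == pytest.approx(pair_splay(b, a), rel=1e-12)


def test_pair_splay_rotation_invariant():
    """In-plane rigid rotation of positions, directors and normals."""
    rng = np.random.default_rng(42)
    phi = 1.1
    R2 = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    R3 = np.eye(3)
    R3[:2, :2] = R2
    z = np.array([0.0, 0.0, 1.0])

    def rand_dir():
        v = z + np.concatenate([rng.normal(scale=0.2, size=2), [0]])
        return v / np.linalg.norm(v)

    pa, pb = rng.uniform(0, 5, 2), rng.uniform(0, 5, 2)
    na, nb, Na, Nb = rand_dir(), rand_dir(), rand_dir(), rand_dir()
    s0 = pair_splay(director(pa, na, Na), director(pb, nb, Nb, lid=1))
    s1 = pair_splay(director(R2 @ pa, R3 @ na, R3 @ Na),
                    director(R2 @ pb, R3 @ nb, R3 @ Nb, lid=1))
    assert s1 == pytest.approx(s0, rel=1e-12)


def test_pair_splay_flat_field_zero_any_h():
    z = np.array([0.0, 0.0, 1.0])
    for h in (0.3, 1.0, 2.5):
        a = director([0, 0], z, z)
        b = director([h, 0], z, z, lid=1)
        assert pair_splay(a, b) == 0.0


def test_pair_splay_coincident_error():
    z = np.array([0.0, 0.0, 1.0])
    a = director([1, 1], z, z)
    b = director([1, 1], z, z, lid=1)
    with pytest.raises(DegenerateLipidError):
        pair_splay(a, b)


def test_pair_splay_sum_convention():
    delta, h = 0.1, 1.0
    z = np.array([0.0, 0.0, 1.0])
    nb = np.array([np.sin(delta), 0.0, np.cos(delta)])
    a = director([0, 0], z, z)
    b = director([h, 0], nb, z, lid=1)
    diff = pair_splay(a, b, convention="difference")
    s = pair_splay(a, b, convention="sum")
    assert diff == pytest.approx(s)  # normals identical: conventions agree
    Nb = np.array([np.sin(0.05), 0.0, np.cos(0.05)])
    b2 = director([h, 0], nb, Nb, lid=1)
    assert pair_splay(a, b2, convention="difference") != pytest.approx(
        pair_splay(a, b2, convention="sum"))


# ---------------------------------------------------------------------------
# distribution and inversion
# ---------------------------------------------------------------------------

def test_splay_distribution_normalized():
    s = generate_splay_samples(12.0, 0.65, n=20000, seed=1)
    dist = splay_distribution(s, A_l=0.65)
    assert np.sum(dist.P * dist.bin_width) == pytest.approx(1.0, rel=1e-12)


def test_fit_splay_modulus_oracle():
    K_c, A_l = 12.0, 0.65
    s = generate_splay_samples(K_c, A_l, n=100000, seed=2)
    dist = splay_distribution(s, A_l)
    est = fit_splay_modulus(dist)
    K_hat = est.extras["K_c_monolayer_kBT"]
    # independent oracle: variance inversion
    K_oracle = 1.0 / (A_l * s.var())
    assert K_hat == pytest.approx(K_oracle, rel=0.05)
    assert K_hat == pytest.approx(K_c, rel=0.05)
    assert est.kappa == 2.0 * K_hat  # bilayer doubling, exact


def test_fit_splay_modulus_degenerate():
    with pytest.raises(FitError):
        splay_distribution(np.zeros(1000), A_l=0.65)


def test_monolayer_to_bilayer():
    assert monolayer_to_bilayer(12.12) == pytest.approx(24.24)


# ---------------------------------------------------------------------------
# multi-component combination
# ---------------------------------------------------------------------------

def test_combine_single_species_identity():
    pm = PairModuli(phi={("A", "A"): 10}, chi={("A", "A"): 20.0})
    assert combine_pair_moduli(pm) == pytest.approx(20.0)


def test_combine_equal_chis():
    pm = PairModuli(phi={"AA": 7, "AB": 3}, chi={"AA": 15.0, "AB": 15.0})
    assert combine_pair_moduli(pm) == pytest.approx(15.0)


def test_combine_hand_arithmetic():
    pm = PairModuli(phi={"11": 100, "12": 50}, chi={"11": 10.0, "12": 20.0})
    assert combine_pair_moduli(pm) == pytest.approx(12.0, rel=1e-12)


def test_combine_rejects_zero_chi():
    with pytest.raises(ConfigurationError):
        PairModuli(phi={"AA": 1}, chi={"AA": 0.0})


@given(
    phis=st.lists(st.integers(1, 100), min_size=1, max_size=5),
    chis=st.lists(st.floats(0.5, 50.0), min_size=5, max_size=5),
)
@settings(max_examples=50, deadline=None)
def test_combine_bounded_by_extremes(phis, chis):
    keys = [str(i) for i in range(len(phis))]
    pm = PairModuli(phi=dict(zip(keys, phis)),
                    chi=dict(zip(keys, chis[:len(phis)])))
    k = combine_pair_moduli(pm)
    vals = list(pm.chi.values())
    assert min(vals) - 1e-9 <= k <= max(vals) + 1e-9


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

def test_rsf_recovery_against_variance_oracle():
    params = SynthParams(L=16.0, n_lipids=256, kappa=30.0, a=0.02,
                         tilt_sd=0.08, n_frames=30, seed=43)
    traj, _ = generate_trajectory(params)
    a = assign_leaflets_trajectory(traj)
    est = rsf_modulus(traj, a)
    all_s = []
    for frame in traj.frames():
        f = director_field(frame, a, 1.5)
        pairs = neighbor_pairs(frame, a, 1.2)
        s, _ = splay_samples(f, pairs)
        all_s.append(s)
    samples = np.concatenate(all_s)
    A_l = float(apl_series(traj, a).mean())
    K_oracle = 1.0 / (A_l * samples.var())
    assert est.extras["K_c_monolayer_kBT"] == pytest.approx(K_oracle, rel=0.10)


def test_rsf_multicomponent_combines():
    params = SynthParams(L=12.0, n_lipids=144, kappa=30.0, a=0.02,
                         tilt_sd=0.08, n_frames=40, seed=44,
                         species=("AAA", "BBB"))
    traj, _ = generate_trajectory(params)
    a = assign_leaflets_trajectory(traj)
    est = rsf_modulus(traj, a)
    assert set(est.extras["pair_counts"]) == {"AAA|AAA", "AAA|BBB", "BBB|BBB"}
    chis = [v["K_c_monolayer_kBT"] for v in est.extras["per_pair"].values()]
    assert min(chis) <= est.extras["K_c_monolayer_kBT"] <= max(chis)
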