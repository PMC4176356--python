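"""Energy terms, frame geometry and analytic-gradient contracts."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from twistloop import _geometry as geom
from twistloop.chain import (
    BeadChain,
    ForceField,
    PolymerSystem,
    affinity_energy,
    dihedral_angle,
    excluded_volume_energy,
    forces_and_torques,
    k_bend_from_persistence,
    torsion_energy,
    total_energy,
)
from twistloop.state import FrameState


def _realisable(pos, tw):
    """Project a twist assignment onto the closed-ribbon realisable set."""
    a = geom.bishop_frames(pos)
    th = geom.theta_from_junction_twists(pos, tw, a, tol=np.inf)
    return geom.junction_twists_from_theta(pos, th, a)


def _random_ring(rng, n=12, wiggle=0.25):
    """Closed ring: perturbed circle, bond lengths regularised to ~1."""
    base = BeadChain.circle(n).positions
    pos = base + wiggle * rng.standard_normal((n, 3))
    # crude bond regularisation so the chain passes validate()
    for _ in range(200):
        e = np.roll(pos, -1, axis=0) - pos
        b = np.linalg.norm(e, axis=1)
        corr = 0.25 * (b - 1.0)[:, None] * (e / b[:, None])
        pos += corr - np.roll(corr, 1, axis=0)
        pos -= pos.mean(axis=0)
        if abs(b - 1).max() < 0.02:
            break
    return pos


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "phi,k,phi0,expected",
    [(0.3, 65.0, 0.3, 0.0), (np.pi + 0.1, 65.0, 0.1, 65.0), (np.pi / 2, 50.0, 0.0, 25.0)],
)
def test_torsion_energy_values(phi, k, phi0, expected):
    assert torsion_energy(phi, k, phi0) == pytest.approx(expected, abs=1e-12)


def test_torsion_energy_periodic():
    phis = np.linspace(-3, 3, 13)
    assert np.allclose(
        torsion_energy(phis + 2 * np.pi, 65.0), torsion_energy(phis, 65.0), atol=1e-12
    )


def test_affinity_energy_well_depth_and_cut():
    rmin = 2.0 ** (1.0 / 6.0)
    assert affinity_energy(rmin, epsilon=10.0) == pytest.approx(-10.0, abs=1e-12)
    assert affinity_energy(2.0, epsilon=12.0) == 0.0
    assert affinity_energy(5.0, epsilon=12.0) == 0.0
    # direct hand evaluation of the 12-6 formula at r = 1.5 d, eps = 8
    sr6 = (1.0 / 1.5) ** 6
    assert affinity_energy(1.5, epsilon=8.0) == pytest.approx(32.0 * (sr6 * sr6 - sr6))
    with pytest.raises(ValueError):
        affinity_energy(-0.5, epsilon=1.0)


def test_excluded_volume_is_purely_repulsive():
    r = np.linspace(0.8, 3.0, 200)
    v = excluded_volume_energy(r)
    assert np.all(v >= 0)
    assert v[-1] == 0.0


def test_k_bend_inversion_recovers_tangent_correlation():
    # <cos beta> under V = k(1-cos beta) equals coth(k)-1/k; inversion should
    # return the k whose correlation length is exactly P bonds.
    for p in (2.0, 17.0):
        k = k_bend_from_persistence(p)
        mean_cos = 1.0 / np.tanh(k) - 1.0 / k
        assert -1.0 / np.log(mean_cos) == pytest.approx(p, rel=1e-9)


# ---------------------------------------------------------------------------
# dihedral / frame transport
# ---------------------------------------------------------------------------

def test_dihedral_zero_for_untwisted_straightish_junction():
    chain = BeadChain.circle(12)
    for j in (0, 5, 11):
        assert dihedral_angle(chain, j) == pytest.approx(0.0, abs=1e-10)


def test_dihedral_finite_at_right_angle_bend():
    # two consecutive segments bent by exactly 90 degrees, zero twist
    n = 8
    pos = BeadChain.circle(n).positions.copy()
    pos[2] = pos[1] + np.array([0.0, 0.0, 1.0])  # force a right angle at bead 1
    chain = BeadChain(positions=pos)
    t = geom.ring_tangents(pos)
    assert abs(np.dot(t[0], t[1])) < 0.3  # genuinely strongly bent
    val = dihedral_angle(chain, 1)
    assert np.isfinite(val)


def test_dihedral_round_trips_stored_twists():
    rng = np.random.default_rng(3)
    pos = _random_ring(rng)
    tw = 0.4 * rng.standard_normal(len(pos))
    tw -= tw.mean()  # keep the assignment realisable on a closed ring
    chain = BeadChain(positions=pos, twist_angles=tw)
    got = np.array([dihedral_angle(chain, j) for j in range(len(pos))])
    defect = got - tw
    # reconstruction spreads any closure defect uniformly; allow that shift
    assert np.std(defect) == pytest.approx(0.0, abs=1e-8)


def test_parallel_transport_quaternion_oracle():
    """Transport must agree with an independent quaternion implementation."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        t1 = rng.standard_normal(3)
        t1 /= np.linalg.norm(t1)
        t2 = rng.standard_normal(3)
        t2 /= np.linalg.norm(t2)
        v = rng.standard_normal(3)
        v -= np.dot(v, t1) * t1
        axis = np.cross(t1, t2)
        s = np.linalg.norm(axis)
        ang = np.arctan2(s, np.dot(t1, t2))
        q = Rotation.from_rotvec(axis / s * ang)
        assert np.allclose(geom.parallel_transport(v, t1, t2), q.apply(v), atol=1e-6)


def test_degenerate_segment_rejected():
    pos = BeadChain.circle(8).positions.copy()
    pos[3] = pos[2]
    with pytest.raises(Exception):
        total_energy(BeadChain(positions=pos), ForceField.dna())


# ---------------------------------------------------------------------------
# assembled energy
# ---------------------------------------------------------------------------

def test_relaxed_circle_is_force_free_and_energy_free():
    n = 16
    ff = ForceField.dna()
    chain = BeadChain.circle(n)
    e = total_energy(chain, ff)
    assert e.bond == pytest.approx(0.0, abs=1e-12)
    assert e.torsion == pytest.approx(0.0, abs=1e-12)
    assert e.affinity == 0.0
    f, tq = forces_and_torques(chain, ff)
    assert np.abs(f).max() < 1e-8
    assert np.abs(tq).max() < 1e-12


def test_affinity_zero_beyond_cut_and_for_unlabelled_pairs():
    chain = BeadChain.circle(20, dlk=0.0)
    chain.special_sites = {"enhancer": 0, "promoter": 10}
    ff = ForceField.dna(epsilon=10.0)
    # sites are diametrically opposed: distance ~ 6.4 d > r_cut
    e = total_energy(chain, ff)
    assert e.affinity == 0.0
    # no labels -> no affinity term regardless of epsilon
    bare = BeadChain.circle(20)
    assert total_energy(bare, ff).affinity == 0.0


def test_energy_breakdown_total_is_sum():
    rng = np.random.default_rng(5)
    chain = BeadChain(positions=_random_ring(rng), twist_angles=0.1 * rng.standard_normal(12))
    chain.special_sites = {"enhancer": 0, "promoter": 5}
    e = total_energy(chain, ForceField.dna(epsilon=4.0))
    assert e.total == pytest.approx(
        e.bond + e.bend + e.torsion + e.excluded_volume + e.affinity, abs=1e-9
    )


def test_energy_invariant_under_rigid_motion():
    rng = np.random.default_rng(7)
    pos = _random_ring(rng)
    tw = _realisable(pos, 0.2 * rng.standard_normal(len(pos)))
    ff = ForceField.dna(epsilon=6.0)
    chain = BeadChain(positions=pos, twist_angles=tw,
                      special_sites={"enhancer": 1, "promoter": 7})
    e0 = total_energy(chain, ff).total
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = BeadChain(positions=pos @ rot.T + np.array([3.0, -2.0, 5.0]),
                      twist_angles=tw, special_sites=chain.special_sites)
    assert total_energy(moved, ff).total == pytest.approx(e0, abs=1e-9)


def test_brute_force_energy_oracle_8_bead_ring():
    """Independent brute-force summation over every junction and pair."""
    rng = np.random.default_rng(13)
    n = 8
    pos = _random_ring(rng, n=n, wiggle=0.15)
    tw = _realisable(pos, 0.3 * rng.standard_normal(n))
    ff = ForceField(k_bend=5.0, k_dihedral=30.0, epsilon=3.0)
    chain = BeadChain(positions=pos, twist_angles=tw,
                      special_sites={"enhancer": 0, "promoter": 4})
    e = total_energy(chain, ff)

    edges = np.roll(pos, -1, axis=0) - pos
    blen = np.linalg.norm(edges, axis=1)
    t = edges / blen[:, None]
    exp_bond = 0.5 * ff.k_bond * np.sum((blen - 1.0) ** 2)
    exp_bend = ff.k_bend * sum(1 - np.dot(t[i], t[(i + 1) % n]) for i in range(n))
    exp_tor = sum(torsion_energy(tw[i], ff.k_dihedral) for i in range(n))
    exp_ev, exp_aff = 0.0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (j - i) % n in (1, n - 1):
                continue
            r = np.linalg.norm(pos[j] - pos[i])
            if (i, j) == (0, 4):
                exp_aff += affinity_energy(r, ff.epsilon)
            else:
                exp_ev += excluded_volume_energy(r)
    assert e.bond == pytest.approx(exp_bond, abs=1e-9)
    assert e.bend == pytest.approx(exp_bend, abs=1e-9)
    assert e.torsion == pytest.approx(exp_tor, abs=1e-9)
    assert e.excluded_volume == pytest.approx(exp_ev, abs=1e-9)
    assert e.affinity == pytest.approx(exp_aff, abs=1e-9)


# ---------------------------------------------------------------------------
# analytic gradients vs finite differences
# ---------------------------------------------------------------------------

def _fd_check(system, ff, rtol=1e-5, h=2e-6):
    st = FrameState.from_system(system)
    f, tq = st.forces(ff)
    m = len(st.positions)
    scale = max(np.abs(f).max(), np.abs(tq).max(), 1.0)
    for idx in range(0, m, max(1, m // 6)):
        for axis in range(3):
            dp = np.zeros((m, 3))
            dp[idx, axis] = h
            ep = st.energy_at(ff, positions=st.positions + dp)
            em = st.energy_at(ff, positions=st.positions - dp)
            num = -(ep - em) / (2 * h)
            assert f[idx, axis] == pytest.approx(num, abs=rtol * scale + 1e-7)
        dth = np.zeros(m)
        dth[idx] = h
        ep = st.energy_at(ff, theta=st.theta + dth)
        em = st.energy_at(ff, theta=st.theta - dth)
        num = -(ep - em) / (2 * h)
        assert tq[idx] == pytest.approx(num, abs=rtol * scale + 1e-7)


def test_forces_match_finite_differences_random_chains():
    rng = np.random.default_rng(23)
    for trial in range(6):
        n = int(rng.integers(8, 20))
        pos = _random_ring(rng, n=n, wiggle=0.2)
        tw = _realisable(pos, 0.3 * rng.standard_normal(n))
        chain = BeadChain(positions=pos, twist_angles=tw,
                          special_sites={"enhancer": 0, "promoter": n // 2})
        ff = ForceField(k_bend=float(rng.uniform(2, 20)),
                        k_dihedral=float(rng.uniform(20, 70)),
                        epsilon=float(rng.uniform(0, 8)))
        _fd_check(chain, ff)


def test_net_force_is_zero():
    rng = np.random.default_rng(29)
    pos = _random_ring(rng, n=14, wiggle=0.25)
    tw = _realisable(pos, 0.4 * rng.standard_normal(14))
    chain = BeadChain(positions=pos, twist_angles=tw)
    f, _ = forces_and_torques(chain, ForceField.dna())
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


def test_tethered_pair_forces_match_finite_differences():
    rng = np.random.default_rng(31)
    a = BeadChain(positions=_random_ring(rng, n=10, wiggle=0.1))
    b = BeadChain(positions=_random_ring(rng, n=10, wiggle=0.1) + np.array([4.0, 0, 0]))
    sys_ = PolymerSystem(chains=[a, b], extra_bonds=[(0, 10)],
                         affinity_pairs=[(2, 13)])
    _fd_check(sys_, ForceField(k_bend=4.0, k_dihedral=40.0, epsilon=5.0))
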