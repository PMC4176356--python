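"""Integrator physics: determinism, fluctuation-dissipation, equilibration."""
import numpy as np
import pytest
from scipy import stats

from twistloop.chain import BeadChain, ForceField, PolymerSystem, total_energy
from twistloop.dynamics import (
    Schedule,
    SimulationBox,
    bd_step,
    estimate_equilibration,
    run,
)
from twistloop.topology import writhe_series


def _open_chain(positions):
    ch = BeadChain(positions=np.asarray(positions, float), closed=False)
    return PolymerSystem(chains=[ch])


def test_schedule_validation():
    with pytest.raises(ValueError):
        Schedule(n_steps=-1)
    with pytest.raises(ValueError):
        Schedule(n_steps=10, dt=0.0)
    with pytest.raises(ValueError):
        SimulationBox(edge_length=2.0, periodic=True)


def test_zero_steps_returns_initial_frame_only():
    chain = BeadChain.circle(12)
    traj = run(chain, ForceField.dna(), None, Schedule(n_steps=0, seed=1))
    assert traj.n_frames == 1
    assert np.allclose(traj.positions[0], chain.positions)


def test_determinism_same_seed_identical_trajectories():
    ff = ForceField.dna(epsilon=4.0)
    trajs = []
    for _ in range(2):
        chain = BeadChain.circle(60, dlk=-3.0)
        chain.special_sites = {"enhancer": 0, "promoter": 30}
        trajs.append(run(chain, ff, None,
                         Schedule(n_steps=20_000, sample_every=500, seed=42)))
    assert np.array_equal(trajs[0].positions, trajs[1].positions)
    assert np.array_equal(trajs[0].twists, trajs[1].twists)
    # different seed diverges
    chain = BeadChain.circle(60, dlk=-3.0)
    chain.special_sites = {"enhancer": 0, "promoter": 30}
    other = run(chain, ff, None, Schedule(n_steps=20_000, sample_every=500, seed=43))
    assert not np.array_equal(trajs[0].positions, other.positions)


def test_zero_temperature_equilibrium_state_is_stationary():
    chain = BeadChain.circle(20)
    out = bd_step(chain, ForceField.dna(), None, dt=1e-4, seed=3, n_steps=50, kT=0.0)
    assert np.allclose(out.chains[0].positions, chain.positions, atol=1e-7)


def test_free_bead_diffusion_matches_einstein_relation():
    """MSD of a single free bead: <dr^2> = 6 (k_BT/gamma) t."""
    sys_ = _open_chain([[0.0, 0.0, 0.0]])
    sched = Schedule(n_steps=400_000, dt=5e-4, sample_every=200, seed=11,
                     equilibration_multiple=0)
    traj = run(sys_, ForceField.dna(), None, sched, check_topology=False)
    steps = np.diff(traj.positions[:, 0, :], axis=0)  # independent increments
    dt_s = traj.times[1] - traj.times[0]
    per_dim = steps.ravel()
    var = per_dim.var()
    expected = 2.0 * 1.0 * dt_s  # 2 D dt per dimension, D = kT/gamma = 1
    se = expected * np.sqrt(2.0 / len(per_dim))
    assert abs(var - expected) < 3.0 * se


def test_harmonic_bond_extension_variance_matches_boltzmann():
    """Dimer bond: var(b - b0) = k_BT / k_bond at equilibrium."""
    sys_ = _open_chain([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    ff = ForceField.dna()  # k_bond = 200
    sched = Schedule(n_steps=800_000, dt=5e-5, sample_every=100, seed=13,
                     equilibration_multiple=0)
    traj = run(sys_, ff, None, sched, check_topology=False)
    b = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
    b = b[50:]  # discard the short transient
    # radial measure shifts the mean but not the leading-order variance
    var = b.var()
    expected = 1.0 / ff.k_bond
    se = expected * np.sqrt(2.0 / len(b))
    assert abs(var - expected) < 3.0 * se + 0.02 * expected


def test_bending_unit_samples_boltzmann_distribution():
    """Three-bead bending unit: the bend angle distribution must match
    exp(-k_bend (1 - cos beta)) sin(beta) (KS test, ~1e4 near-independent
    samples)."""
    sys_ = _open_chain([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    k_bend = 3.0
    ff = ForceField(k_bend=k_bend, k_dihedral=10.0)
    sched = Schedule(n_steps=6_000_000, dt=2e-4, sample_every=600, seed=17,
                     equilibration_multiple=0)
    traj = run(sys_, ff, None, sched, check_topology=False)
    e1 = traj.positions[:, 1] - traj.positions[:, 0]
    e2 = traj.positions[:, 2] - traj.positions[:, 1]
    cosb = np.sum(e1 * e2, axis=1) / (
        np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    )
    beta = np.arccos(np.clip(cosb[20:], -1, 1))
    grid = np.linspace(0, np.pi, 2000)
    pdf = np.exp(-k_bend * (1 - np.cos(grid))) * np.sin(grid)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    res = stats.kstest(beta, lambda x: np.interp(x, grid, cdf))
    assert res.pvalue > 0.01


def test_relaxed_ring_has_zero_mean_writhe():
    """An achiral (dLk = 0) ring ensemble has <Wr> = 0 by symmetry."""
    chain = BeadChain.circle(60)
    traj = run(chain, ForceField(k_bend=3.0, k_dihedral=10.0), None,
               Schedule(n_steps=400_000, dt=5e-4, sample_every=500, seed=19,
                        equilibration_multiple=0))
    wr = writhe_series(traj)[40:]
    tau = estimate_equilibration(wr)
    n_eff = len(wr) / max(tau, 1.0)
    se = wr.std() / np.sqrt(max(n_eff, 1.0))
    assert abs(wr.mean()) < 3.0 * se + 1e-3


def test_topology_conserved_along_supercoiled_run():
    """Lk = Tw + Wr drift below 0.05 turns across a supercoiled trajectory."""
    from twistloop.scenarios import make_plasmid

    sc = make_plasmid(-15, 0.0, seed=5, n=170)
    traj = sc.simulate(150_000, seed=55)
    assert traj.metadata["lk_drift"] < 0.05


def test_pbc_energy_invariant_under_box_translation():
    rng = np.random.default_rng(23)
    base = BeadChain.circle(24)
    a = BeadChain(positions=base.positions + rng.uniform(0, 5, 3))
    b = BeadChain(positions=base.positions + rng.uniform(0, 5, 3))
    sys_ = PolymerSystem(chains=[a, b])
    box = SimulationBox(edge_length=9.0, periodic=True)
    ff = ForceField.dna()
    e0 = total_energy(sys_, ff, box).total
    shifted = PolymerSystem(chains=[
        BeadChain(positions=a.positions + np.array([9.0, 0.0, -9.0])),
        BeadChain(positions=b.positions),
    ])
    assert total_energy(shifted, ff, box).total == pytest.approx(e0, abs=1e-9)


def test_kernel_forces_match_reference_implementation():
    """The compiled force kernel and the numpy reference must agree to
    rounding on a twisted ring and on a tethered two-ring system."""
    from twistloop import _geometry as geom
    from twistloop import _kernels as K
    from twistloop.dynamics import _kernel_arrays
    from twistloop.state import FrameState

    rng = np.random.default_rng(31)
    base = BeadChain.circle(16).positions
    pos = base + 0.15 * rng.standard_normal(base.shape)
    for _ in range(200):
        e = np.roll(pos, -1, axis=0) - pos
        bl = np.linalg.norm(e, axis=1)
        corr = 0.25 * (bl - 1)[:, None] * (e / bl[:, None])
        pos += corr - np.roll(corr, 1, axis=0)
    a_dirs = geom.bishop_frames(pos)
    th = geom.theta_from_junction_twists(pos, 0.3 * rng.standard_normal(16),
                                         a_dirs, tol=np.inf)
    tw = geom.junction_twists_from_theta(pos, th, a_dirs)
    chain = BeadChain(positions=pos, twist_angles=tw,
                      special_sites={"enhancer": 0, "promoter": 8})
    ff = ForceField(k_bend=6.0, k_dihedral=45.0, epsilon=7.0)
    sys_ = PolymerSystem(chains=[chain])
    st = FrameState.from_system(sys_)
    f_ref, tq_ref = st.forces(ff)
    phi_ref = st.junction_twists()

    p, theta, dA, dT, rs, rc, xb, ap = _kernel_arrays(sys_)
    m = len(p)
    F = np.zeros((m, 3))
    tq = np.zeros(m)
    phi = np.zeros(m)
    scratch = (np.empty((m, 3)), np.empty(m), np.empty((m, 3)))
    ia = np.empty(m * 64, dtype=np.int64)
    ja = np.empty(m * 64, dtype=np.int64)
    ring_of, loc, ring_n, aff_flag = K.bd_init(p, ap, rs)
    npairs = K._build_pairs(p, -1.0, K.WCA_CUT + K.SKIN, ring_of, loc,
                            ring_n, rc, aff_flag, ia, ja)
    status = K._forces(p, theta, dA, dT, rs, rc, ff.k_bond, 1.0, ff.k_bend,
                       ff.k_dihedral, np.ones(m), np.zeros(m), 1.0, 1.0,
                       ff.epsilon, ff.r_cut, xb, ap, -1.0, ia, ja, npairs,
                       F, tq, phi, *scratch, 1, 500.0)
    assert status == 0
    assert np.abs(F - f_ref).max() < 1e-10
    assert np.abs(tq - tq_ref).max() < 1e-10
    assert np.abs(phi - phi_ref).max() < 1e-10


# ---------------------------------------------------------------------------
# equilibration-time estimator
# ---------------------------------------------------------------------------

def test_iat_white_noise_is_one_sample():
    rng = np.random.default_rng(3)
    tau = estimate_equilibration(rng.standard_normal(20_000))
    assert tau == pytest.approx(1.0, abs=0.15)


@pytest.mark.parametrize("rho", [0.5, 0.9])
def test_iat_ar1_matches_closed_form(rho):
    """AR(1): integrated autocorrelation time (1+rho)/(1-rho) within 20%."""
    rng = np.random.default_rng(7)
    n = 200_000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    tau = estimate_equilibration(x)
    expected = (1 + rho) / (1 - rho)
    assert tau == pytest.approx(expected, rel=0.2)


def test_iat_constant_series_flagged_nonconvergent():
    assert estimate_equilibration(np.ones(500)) == np.inf


def test_iat_requires_minimum_length():
    with pytest.raises(ValueError):
        estimate_equilibration(np.arange(50.0))
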