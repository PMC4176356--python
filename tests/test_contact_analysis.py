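"""Telegraph construction, dwell statistics and derived contact indices."""
import numpy as np
import pytest
from scipy import stats

from twistloop.chain import BeadChain, PolymerSystem
from twistloop.contacts import (
    DwellStats,
    TelegraphSignal,
    dwell_stats,
    enhancement_index,
    phase_diagram,
    preference_ratio,
    telegraph,
)
from twistloop.dynamics import SimulationBox, Trajectory
from twistloop.scenarios import make_markov_telegraph


def _toy_trajectory(distances, periodic_edge=None):
    """Two single-bead rings separated by the given distances (in d)."""
    n = len(distances)
    pos = np.zeros((n, 2, 3))
    pos[:, 1, 0] = distances
    box = (SimulationBox(edge_length=periodic_edge, periodic=True)
           if periodic_edge else SimulationBox())
    tmpl = PolymerSystem(chains=[
        BeadChain(positions=np.zeros((1, 3)), closed=False),
        BeadChain(positions=np.array([[distances[0], 0.0, 0.0]]), closed=False),
    ])
    return Trajectory(times=np.arange(n, dtype=float) + 1.0,
                      positions=pos, twists=np.zeros((n, 2)),
                      ring_start=np.array([0, 1, 2]), template=tmpl, box=box)


# ---------------------------------------------------------------------------
# telegraph construction
# ---------------------------------------------------------------------------

def test_contact_threshold_six_nm_for_dna_beads():
    # centre-centre 5.9 nm -> on, 6.1 nm -> off, for 3 nm beads (d units)
    traj = _toy_trajectory([5.9 / 3.0, 6.1 / 3.0, 0.0])
    sig = telegraph(traj, 0, 1, equilibrated=False)
    assert sig.samples.tolist() == [True, False, True]


def test_telegraph_uses_minimum_image_distances():
    traj = _toy_trajectory([9.5, 0.5], periodic_edge=10.0)
    sig = telegraph(traj, 0, 1, equilibrated=False)
    # 9.5 in a 10-box is 0.5 away through the boundary
    assert sig.samples.tolist() == [True, True]


def test_telegraph_rejects_missing_site_and_bad_threshold():
    traj = _toy_trajectory([1.0, 2.0])
    with pytest.raises(KeyError):
        telegraph(traj, 0, 5)
    with pytest.raises(ValueError):
        telegraph(traj, 0, 1, threshold=0.5)


# ---------------------------------------------------------------------------
# dwell statistics
# ---------------------------------------------------------------------------

def test_dwell_stats_hand_enumerated_example():
    sig = TelegraphSignal(np.array([1, 1, 0, 0, 0, 1, 1, 1], bool), sample_dt=1.0)
    ds = dwell_stats(sig)
    assert ds.fraction_on == pytest.approx(5.0 / 8.0)
    # both on-runs touch the boundary (censored): mean on-time flagged
    assert np.isnan(ds.mean_t_on)
    assert ds.n_on_events == 0
    # one interior off-run of length 3
    assert ds.mean_t_off == pytest.approx(3.0)
    assert ds.n_off_events == 1


def test_dwell_stats_all_on_flags_absent_state():
    ds = dwell_stats(TelegraphSignal(np.ones(100, bool), sample_dt=0.5))
    assert ds.fraction_on == 1.0
    assert np.isnan(ds.mean_t_off)
    assert np.isnan(ds.mean_t_on)  # the single on-run is fully censored


def test_dwell_stats_too_short_signal_rejected():
    with pytest.raises(ValueError):
        dwell_stats(TelegraphSignal(np.array([True]), sample_dt=1.0))


def test_markov_telegraph_estimators_recover_closed_forms():
    """fraction_on -> k_on/(k_on+k_off), <t_on> -> 1/k_off, <t_off> -> 1/k_on
    within 3 standard errors (plus the sampling-grid discretisation)."""
    k_on, k_off = 0.2, 0.1
    dt = 0.1
    sig = make_markov_telegraph(k_on, k_off, duration=40_000.0, sample_dt=dt, seed=5)
    ds = dwell_stats(sig)

    p = k_on / (k_on + k_off)
    tau_c = 1.0 / (k_on + k_off)
    n_eff = sig.duration / (2.0 * tau_c)
    se_p = np.sqrt(p * (1 - p) / n_eff)
    assert abs(ds.fraction_on - p) < 3 * se_p

    se_on = (1.0 / k_off) / np.sqrt(ds.n_on_events)
    assert abs(ds.mean_t_on - 1.0 / k_off) < 3 * se_on + dt
    se_off = (1.0 / k_on) / np.sqrt(ds.n_off_events)
    assert abs(ds.mean_t_off - 1.0 / k_on) < 3 * se_off + dt


def test_symmetric_rates_give_half_occupancy():
    sig = make_markov_telegraph(0.3, 0.3, duration=30_000.0, sample_dt=0.1, seed=9)
    ds = dwell_stats(sig)
    assert ds.fraction_on == pytest.approx(0.5, abs=0.02)


def test_markov_dwell_times_are_exponential():
    """Exact (uncensored) dwell durations of the generator pass a KS test
    against their exponential laws at ~1e4 events."""
    _, on_durs, off_durs = make_markov_telegraph(
        1.0, 1.0, duration=21_000.0, sample_dt=1.0, seed=21, return_events=True
    )
    assert min(len(on_durs), len(off_durs)) > 4000
    assert stats.kstest(on_durs, "expon", args=(0, 1.0)).pvalue > 0.01
    assert stats.kstest(off_durs, "expon", args=(0, 1.0)).pvalue > 0.01


def test_empty_duration_gives_empty_signal():
    sig = make_markov_telegraph(0.2, 0.1, duration=0.0, sample_dt=0.5, seed=1)
    assert len(sig) == 0


def test_fraction_on_invariant_under_time_reversal():
    sig = make_markov_telegraph(0.4, 0.2, duration=2_000.0, sample_dt=0.5, seed=31)
    rev = TelegraphSignal(sig.samples[::-1].copy(), sig.sample_dt)
    assert dwell_stats(rev).fraction_on == dwell_stats(sig).fraction_on


def test_subsampling_changes_fraction_on_by_less_than_one_sample_weight():
    sig = make_markov_telegraph(0.4, 0.2, duration=2_000.0, sample_dt=0.5, seed=33)
    sub = TelegraphSignal(sig.samples[::2].copy(), sig.sample_dt * 2)
    f_full = dwell_stats(sig).fraction_on
    f_sub = dwell_stats(sub).fraction_on
    # subsample estimates the same mean; allow binomial-noise-scale deviation
    assert abs(f_full - f_sub) < 3.0 / np.sqrt(len(sub))


def test_fraction_on_estimator_bias_below_two_percent():
    """Across a rate grid, the fraction-on estimator agrees with the
    stationary closed form to < 2% at ~1e4 switching events."""
    for k_on, k_off in [(0.5, 0.5), (0.8, 0.2), (0.2, 0.6)]:
        tau = 1.0 / k_on + 1.0 / k_off
        duration = 1.0e4 * tau / 2.0
        sig = make_markov_telegraph(k_on, k_off, duration, sample_dt=tau / 40.0,
                                    seed=int(10 * k_on + 100 * k_off))
        ds = dwell_stats(sig, n_boot=0) if False else dwell_stats(sig)
        p = k_on / (k_on + k_off)
        assert abs(ds.fraction_on - p) / p < 0.02


# ---------------------------------------------------------------------------
# contact indices
# ---------------------------------------------------------------------------

def _stats(frac, ci=None, n_on=100):
    ci = ci or (frac * 0.9, min(frac * 1.1, 1.0) if frac else 0.01)
    return DwellStats(fraction_on=frac, mean_t_on=1.0, mean_t_off=1.0,
                      median_t_on=1.0, median_t_off=1.0, n_on_events=n_on,
                      n_off_events=n_on, fraction_on_ci=ci)


def test_enhancement_index_arithmetic():
    fold, _ = enhancement_index(_stats(0.6), _stats(0.2))
    assert fold == pytest.approx(3.0)
    fold, _ = enhancement_index(_stats(0.3), _stats(0.3))
    assert fold == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        enhancement_index(_stats(0.3), _stats(0.0, ci=(0.0, 0.0)))


def test_preference_ratio_arithmetic_and_lower_bound():
    r, _, lb = preference_ratio(_stats(0.40), _stats(0.02))
    assert r == pytest.approx(20.0)
    assert not lb
    r, _, lb = preference_ratio(_stats(0.3), _stats(0.3))
    assert r == pytest.approx(1.0)
    # zero denominator: reported as a CI-floor lower bound
    r, ci, lb = preference_ratio(_stats(0.40), _stats(0.0, ci=(0.0, 0.01)))
    assert lb and r == pytest.approx(40.0)
    r, ci, lb = preference_ratio(_stats(0.40), _stats(0.0, ci=(0.0, 0.0)),
                                 n_samples=300)
    assert lb and r == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

def test_phase_diagram_constant_surface():
    dlk = [0, -5, -10]
    eps = [0, 4, 8]
    pd_ = phase_diagram(dlk, eps, np.full((3, 3), 0.5), levels=(0.5,))
    # the whole surface sits at the 0.5 level; the degenerate isoline may be
    # empty or cover the grid, but the surface itself must be flat at 0.5
    assert np.allclose(pd_.surface, 0.5, atol=1e-9)


def test_phase_diagram_recovers_hyperbolic_isolines():
    """f(x, y) = x*y on [0,1]^2: the c-isoline is the hyperbola y = c/x."""
    x = np.linspace(0, 1, 6)
    y = np.linspace(0, 1, 6)
    z = np.outer(x, y)
    pd_ = phase_diagram(x, y, z, levels=(0.25, 0.5))
    for lev in (0.25, 0.5):
        pts = np.vstack(pd_.isolines[lev])
        assert len(pts) > 10
        assert np.allclose(pts[:, 0] * pts[:, 1], lev, atol=0.02)


def test_phase_diagram_monotone_surface_isolines_ordered():
    x = np.linspace(0, 1, 5)
    z = np.add.outer(x, x) / 2.0  # monotone plane
    pd_ = phase_diagram(x, x, z, levels=(0.25, 0.5, 0.75))
    # along the diagonal x = y the crossing points must be ordered
    cross = [np.vstack(pd_.isolines[l])[:, 0].mean() for l in (0.25, 0.5, 0.75)]
    assert cross[0] < cross[1] < cross[2]


def test_phase_diagram_masks_missing_cells():
    x = np.linspace(0, 1, 5)
    z = np.add.outer(x, x) / 2.0
    z[0, 0] = np.nan
    pd_ = phase_diagram(x, x, z, levels=(0.5,))
    assert np.isnan(pd_.surface).any()
    assert len(pd_.isolines[0.5]) >= 1


def test_phase_diagram_rejects_tiny_grid():
    with pytest.raises(ValueError):
        phase_diagram([0], [0, 1], np.zeros((1, 2)))
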