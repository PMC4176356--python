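"""Scenario generators: every initial condition and validation signal used
by the analyses.

The three in-study systems are

* ``plasmid`` -- a 3000 bp DNA ring (340 beads of 3 nm) with enhancer and
  promoter diametrically opposed (180 degrees apart on the circular map);
* ``crowded_loops`` -- 20 copies of an 800 kb chromatin loop (200 beads of
  30 nm, 4000 bp per bead) in a periodic box at 20% bead volume fraction;
* ``tethered_pair`` -- two chromatin loops joined by a single harmonic
  tether bond, one enhancer with two equidistant, equally attractive
  promoters (one per loop), modelling neighbouring topological domains.

Supercoiled rings start from a pre-built interwound (plectonemic)
conformation whose writhe is close to the expected equilibrium partition,
with the residual linking difference stored as uniform material twist so
that Lk = Tw + Wr equals the requested dLk exactly at frame zero.  Starting
instead from a flat, fully twisted circle is supported (``plectonemic
=False``) and converges to the same ensemble, but far more slowly.

A two-state Markov telegraph generator with known rates provides ground
truth for the dwell-time estimators.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro, Boltzmann, calorie

from . import _kernels as K
from .chain import BeadChain, ForceField, PolymerSystem
from .contacts import TelegraphSignal
from .dynamics import Schedule, SimulationBox, run
from .topology import writhe

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "build_plectoneme",
    "sample_open_wlc",
    "make_plasmid",
    "make_crowded_loops",
    "make_tethered_pair",
    "make_separation_sweep",
    "make_markov_telegraph",
    "bp_to_beads",
    "kBT_to_kcal",
    "DNA_BEADS",
    "DNA_BP",
    "CHROMATIN_BEADS",
    "CHROMATIN_BP_PER_BEAD",
]

# DNA plasmid: 3000 bp at 0.34 nm/bp rise -> 1020 nm contour of 3 nm beads
DNA_BP = 3000
DNA_BEADS = 340
DNA_BP_PER_BEAD = DNA_BP / DNA_BEADS
# chromatin: 200 beads x 4000 bp = 800 kb topological domain
CHROMATIN_BEADS = 200
CHROMATIN_BP_PER_BEAD = 4000.0


@dataclass
class ScenarioConfig:
    """Declarative description of a scenario (round-trips through YAML)."""

    kind: str                      # plasmid | crowded_loops | tethered_pair | separation_sweep
    dlk: float = 0.0
    epsilon: float = 0.0           # k_BT
    separation_bp: float | None = None
    n_copies: int = 1
    target_volume_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_volume_fraction is not None and not (
            0.0 < self.target_volume_fraction < 0.5
        ):
            raise ValueError("volume fraction must be in (0, 0.5)")


@dataclass
class Scenario:
    """An initial state bundled with its force field and box."""

    system: PolymerSystem
    ff: ForceField
    box: SimulationBox | None
    config: ScenarioConfig
    contact_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)
    equilibration_multiple: float = 40.0

    def schedule(self, n_steps: int, seed: int | None = None, **kw) -> Schedule:
        kw.setdefault("equilibration_multiple", self.equilibration_multiple)
        return Schedule(n_steps=n_steps,
                        seed=self.config.seed if seed is None else seed, **kw)

    def simulate(self, n_steps: int, seed: int | None = None, **kw):
        return run(self.system, self.ff, self.box,
                   self.schedule(n_steps, seed, **kw),
                   scenario_id=self.config.kind)


# ---------------------------------------------------------------------------
# plectonemic initial conformations
# ---------------------------------------------------------------------------

def _interwound_curve(n: int, n_turns: int, radius: float, fine: int = 12) -> np.ndarray:
    """Closed interwound superhelix (two antiparallel strands + end caps),
    resampled to ``n`` beads of equal bond length ~1."""
    arm = (n - 2.0 * np.pi * radius) / 2.0
    if arm <= 0 or n_turns < 0:
        raise ValueError("ring too short for an interwound superhelix")
    h2 = arm * arm - (2.0 * np.pi * n_turns * radius) ** 2
    if h2 <= 0:
        raise ValueError("too many superhelical turns for this radius")
    height = np.sqrt(h2)

    m = fine * n
    # contour budget per section
    s_arm = arm
    s_cap = np.pi * radius
    total = 2 * s_arm + 2 * s_cap
    ts = np.linspace(0.0, total, m, endpoint=False)
    pts = np.empty((m, 3))
    for k, s in enumerate(ts):
        if s < s_arm:  # strand up
            t = s / s_arm
            ang = 2.0 * np.pi * n_turns * t
            pts[k] = (radius * np.cos(ang), radius * np.sin(ang), height * t)
        elif s < s_arm + s_cap:  # top cap: semicircle through the axis
            v = (s - s_arm) / s_cap * np.pi
            ang = 2.0 * np.pi * n_turns
            p1 = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
            pts[k] = np.cos(v) * p1 + np.array([0.0, 0.0, radius * np.sin(v)])
            pts[k, 2] += height
        elif s < 2 * s_arm + s_cap:  # strand down (antiparallel, offset pi)
            t = (s - s_arm - s_cap) / s_arm
            ang = np.pi + 2.0 * np.pi * n_turns * (1.0 - t)
            pts[k] = (radius * np.cos(ang), radius * np.sin(ang), height * (1.0 - t))
        else:  # bottom cap
            v = (s - 2 * s_arm - s_cap) / s_cap * np.pi
            p1 = np.array([radius * np.cos(np.pi), radius * np.sin(np.pi), 0.0])
            pts[k] = np.cos(v) * p1 + np.array([0.0, 0.0, -radius * np.sin(v)])
    # equal-arclength resampling to n beads
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    targets = np.arange(n) * L / n
    out = np.empty((n, 3))
    for k, s in enumerate(targets):
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, m - 1)
        frac = (s - cum[j]) / max(seg[j], 1e-12)
        out[k] = pts[j] + frac * (pts[(j + 1) % m] - pts[j])
    # rescale so the mean bond length is exactly 1
    b = np.linalg.norm(np.roll(out, -1, axis=0) - out, axis=1)
    return out / b.mean()


def build_plectoneme(n: int, target_writhe: float, rng=None) -> np.ndarray:
    """Interwound conformation with writhe close to ``target_writhe``.

    Scans the number of superhelical turns (adapting the superhelix radius
    when the ring is short) and returns the candidate whose exact writhe is
    closest to the target, randomly oriented when ``rng`` is given.
    """
    if abs(target_writhe) < 1.0:
        raise ValueError("use a circle for nearly relaxed rings")
    best, best_err = None, np.inf
    sign = 1.0 if target_writhe > 0 else -1.0
    # each interwound turn carries roughly two signed crossings
    for n_turns in range(max(1, int(abs(target_writhe) * 0.35)),
                         int(abs(target_writhe) * 1.2) + 2):
        arm = (n - 2.0 * np.pi) / 2.0
        radius = min(1.0, max(0.55, 0.8 * arm / (2.0 * np.pi * n_turns)))
        try:
            pos = _interwound_curve(n, n_turns, radius)
        except ValueError:
            continue
        wr = writhe(pos)
        if np.sign(wr) != sign:
            pos = pos * np.array([1.0, 1.0, -1.0])
            wr = -wr
        err = abs(wr - target_writhe)
        if err < best_err:
            best, best_err, best_wr = pos, err, wr
    if best is None:
        raise ValueError("could not construct an interwound conformation")
    if rng is not None:
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        best = best @ rot.T
    return best - best.mean(axis=0)


def _roll_to_juxtapose(pos: np.ndarray, a: int, b: int) -> np.ndarray:
    """Cyclic re-indexing (slithering phase) bringing beads a and b as close
    together in space as the curve allows."""
    n = len(pos)
    best_k, best_d = 0, np.inf
    for k in range(n):
        d = np.linalg.norm(pos[(a - k) % n] - pos[(b - k) % n])
        if d < best_d:
            best_k, best_d = k, d
    return np.roll(pos, best_k, axis=0)


def _supercoiled_ring(n: int, dlk: float, plectonemic: bool,
                      writhe_target_fraction: float, rng,
                      align_sites: tuple[int, int] | None = None,
                      **chain_kw) -> BeadChain:
    """Ring at linking difference dlk: plectonemic or flat-twisted start.

    The geometric writhe of the constructed conformation is measured and
    the remaining dlk - Wr is stored as uniform material twist, so the
    linking difference is exact from frame zero.

    The slithering phase (which contour position sits at the plectoneme
    apexes) is the slowest mode of a supercoiled ring, far beyond
    desk-scale relaxation, so it is part of the initial condition: drawn
    uniformly by default, or chosen to juxtapose two sites when
    ``align_sites`` is given (contact-start protocol for dwell-time
    measurements).  At dlk = 0 the aligned variant is a writhe-free folded
    (hairpin) ring, the unaligned one a flat circle.
    """
    if dlk == 0 or not plectonemic or abs(dlk) < 3:
        if align_sites is None:
            return BeadChain.circle(n, dlk=dlk, **chain_kw)
        pos = _interwound_curve(n, 0, 0.75)
        pos = _roll_to_juxtapose(pos, *align_sites)
        wr = writhe(pos)
        tw_angles = np.full(n, 2.0 * np.pi * (dlk - wr) / n)
        return BeadChain(positions=pos, twist_angles=tw_angles, **chain_kw)
    pos = build_plectoneme(n, writhe_target_fraction * dlk, rng)
    if align_sites is not None:
        pos = _roll_to_juxtapose(pos, *align_sites)
    elif rng is not None:
        pos = np.roll(pos, int(rng.integers(n)), axis=0)
    wr = writhe(pos)
    tw_angles = np.full(n, 2.0 * np.pi * (dlk - wr) / n)
    return BeadChain(positions=pos, twist_angles=tw_angles, **chain_kw)


# ---------------------------------------------------------------------------
# in-study systems
# ---------------------------------------------------------------------------

def make_plasmid(dlk: float, epsilon: float, seed: int = 0,
                 n: int = DNA_BEADS, plectonemic: bool = True,
                 contact_start: bool = False) -> Scenario:
    """3000 bp plasmid with enhancer/promoter 180 degrees apart on the map.

    DNA parameterization: 3 nm beads, persistence length 17 beads (51 nm),
    dihedral stiffness 65 k_BT.  ``dlk`` in [-20, 20].

    With ``contact_start`` the slithering phase (or, at dlk = 0, a folded
    ring) is chosen so the two sites start juxtaposed: the protocol for
    dwell-time and rebinding measurements, where the relevant comparison is
    how long contacts persist and how quickly they reform.
    """
    if abs(dlk) > 20:
        raise ValueError("plasmid scenarios cover |dLk| <= 20")
    rng = np.random.default_rng(seed)
    chain = _supercoiled_ring(
        n, dlk, plectonemic, writhe_target_fraction=0.8, rng=rng,
        align_sites=(0, n // 2) if contact_start else None,
        bead_diameter_nm=3.0, bp_per_bead=DNA_BP / n,
        special_sites={"enhancer": 0, "promoter": n // 2},
    )
    ff = ForceField.dna(epsilon=epsilon)
    config = ScenarioConfig(kind="plasmid", dlk=dlk, epsilon=epsilon, seed=seed)
    sys_ = PolymerSystem(chains=[chain])
    return Scenario(system=sys_, ff=ff, box=None, config=config,
                    contact_pairs={"EP": (0, n // 2)},
                    equilibration_multiple=40.0)


def _chromatin_chain(n: int, dlk: float, sites: dict[str, int],
                     plectonemic: bool, rng,
                     align_sites: tuple[int, int] | None = None) -> BeadChain:
    return _supercoiled_ring(
        n, dlk, plectonemic, writhe_target_fraction=0.9, rng=rng,
        align_sites=align_sites,
        bead_diameter_nm=30.0, bp_per_bead=CHROMATIN_BP_PER_BEAD,
        special_sites=sites,
    )


def chromatin_loop(dlk: float, epsilon: float, separation_beads: int = 100,
                   seed: int = 0, n: int = CHROMATIN_BEADS,
                   plectonemic: bool = True, contact_start: bool = False,
                   k_dihedral: float = 50.0) -> Scenario:
    """A single dilute 800 kb chromatin loop (control / separation sweep)."""
    if separation_beads > n // 2:
        raise ValueError("separation exceeds half the loop; shorter arc ambiguous")
    rng = np.random.default_rng(seed)
    chain = _supercoiled_ring(
        n, dlk, plectonemic, writhe_target_fraction=0.9, rng=rng,
        align_sites=(0, separation_beads) if contact_start else None,
        bead_diameter_nm=30.0, bp_per_bead=CHROMATIN_BP_PER_BEAD,
        special_sites={"enhancer": 0, "promoter": separation_beads},
    )
    ff = ForceField.chromatin(epsilon=epsilon, k_dihedral=k_dihedral)
    config = ScenarioConfig(kind="separation_sweep", dlk=dlk, epsilon=epsilon,
                            separation_bp=separation_beads * CHROMATIN_BP_PER_BEAD,
                            seed=seed)
    return Scenario(system=PolymerSystem(chains=[chain]), ff=ff, box=None,
                    config=config,
                    contact_pairs={"EP": (0, separation_beads)},
                    equilibration_multiple=10.0)


def make_crowded_loops(dlk: float, epsilon: float, n_copies: int = 20,
                       separation_beads: int = 100,
                       volume_fraction: float = 0.2, seed: int = 0,
                       n: int = CHROMATIN_BEADS, relax_steps: int = 3000,
                       max_tries: int = 8) -> Scenario:
    """Crowded periodic box of chromatin-loop copies.

    The cubic edge is set so the total bead volume fraction equals
    ``volume_fraction`` (20% emulates interphase-nucleus chromatin
    concentration).  Loops are dropped at random positions/orientations and
    pushed apart by a short capped-force relaxation; affinity acts only
    within each loop (one enhancer + one promoter per copy).
    """
    if n_copies < 1:
        raise ValueError("need at least one copy")
    edge = (n_copies * n * (np.pi / 6.0) / volume_fraction) ** (1.0 / 3.0)
    box = SimulationBox(edge_length=float(edge), periodic=True)
    rng = np.random.default_rng(seed)

    for attempt in range(max_tries):
        chains = []
        for c in range(n_copies):
            ch = _chromatin_chain(
                n, dlk, {"enhancer": 0, "promoter": separation_beads},
                plectonemic=True, rng=rng,
            )
            shift = rng.uniform(0.0, edge, size=3)
            chains.append(
                BeadChain(positions=ch.positions + shift,
                          twist_angles=ch.twist_angles,
                          bead_diameter_nm=ch.bead_diameter_nm,
                          bp_per_bead=ch.bp_per_bead,
                          special_sites=dict(ch.special_sites))
            )
        sys_ = PolymerSystem(chains=chains)
        ff = ForceField.chromatin(epsilon=epsilon)
        try:
            # capped push-off to resolve drop-in overlaps, then a short
            # settle phase at the working force cap to restore bond lengths
            pushed = run(
                sys_, ff, box,
                Schedule(n_steps=relax_steps, dt=1e-4, sample_every=max(relax_steps, 1),
                         seed=int(rng.integers(2**31)), force_cap=50.0),
                check_topology=False,
            ).frame(-1)
            relaxed = run(
                pushed, ff, box,
                Schedule(n_steps=relax_steps, dt=2e-4, sample_every=max(relax_steps, 1),
                         seed=int(rng.integers(2**31))),
                check_topology=False,
            ).frame(-1)
        except Exception:
            continue
        config = ScenarioConfig(kind="crowded_loops", dlk=dlk, epsilon=epsilon,
                                separation_bp=separation_beads * CHROMATIN_BP_PER_BEAD,
                                n_copies=n_copies,
                                target_volume_fraction=volume_fraction, seed=seed)
        pairs = {
            f"EP{c}": (c * n + 0, c * n + separation_beads) for c in range(n_copies)
        }
        return Scenario(system=relaxed, ff=ff, box=box, config=config,
                        contact_pairs=pairs, equilibration_multiple=10.0)
    raise RuntimeError(f"packing failed after {max_tries} attempts")


def make_tethered_pair(dlk: float, epsilon: float = 8.0, seed: int = 0,
                       n: int = CHROMATIN_BEADS,
                       contact_start: bool = False,
                       relax_steps: int = 1500) -> Scenario:
    """Two chromatin loops tethered by one harmonic bond: neighbouring
    topological domains.

    Enhancer E sits on loop 1 at bead n/4, promoter P1 (same domain)
    diametrically opposite at bead 3n/4, promoter P2 (neighbouring domain)
    at bead n/4 of loop 2; the tether joins bead 0 of both loops, so both
    promoters are at the same genomic distance (n/2 beads ~ 400 kb) from E,
    P2 measured through the tether.  Both pairs carry the same affinity and
    the two contacts are tracked independently (not mutually exclusive).

    The loop bodies are placed pointing away from each other along the
    tether direction and briefly relaxed.  With ``contact_start`` loop 1's
    slithering phase juxtaposes E and P1 (intra-domain contact-start
    protocol); loop 2's phase is always random.
    """
    rng = np.random.default_rng(seed)
    q = n // 4
    loop1 = _chromatin_chain(
        n, dlk, {"enhancer": q, "promoter_intra": q + n // 2},
        plectonemic=True, rng=rng,
        align_sites=(q, q + n // 2) if contact_start else None,
    )
    loop2 = _chromatin_chain(n, dlk, {"promoter_inter": q},
                             plectonemic=True, rng=rng)

    # orient loop2 so its body points away from loop1 across the tether
    p1 = loop1.positions
    b1 = p1[0]
    w = b1 - p1.mean(axis=0)
    w = w / np.linalg.norm(w)
    p2 = loop2.positions
    b2 = p2[0]
    v = p2.mean(axis=0) - b2
    v = v / np.linalg.norm(v)
    axis = np.cross(v, w)
    s_ = np.linalg.norm(axis)
    if s_ > 1e-9:
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(axis / s_ * np.arctan2(s_, float(np.dot(v, w))))
        p2 = b2 + rot.apply(p2 - b2)
    p2 = p2 - p2[0] + (b1 + 1.05 * w)
    loop2 = BeadChain(positions=p2, twist_angles=loop2.twist_angles,
                      bead_diameter_nm=loop2.bead_diameter_nm,
                      bp_per_bead=loop2.bp_per_bead,
                      special_sites=dict(loop2.special_sites))
    sys_ = PolymerSystem(
        chains=[loop1, loop2],
        extra_bonds=[(0, n)],
        affinity_pairs=[(q, q + n // 2), (q, n + q)],
    )
    ff = ForceField.chromatin(epsilon=epsilon)
    if relax_steps:
        pushed = run(sys_, ff, None,
                     Schedule(n_steps=relax_steps, dt=1e-4,
                              sample_every=relax_steps,
                              seed=int(rng.integers(2**31)), force_cap=50.0),
                     check_topology=False).frame(-1)
        settled = run(pushed, ff, None,
                      Schedule(n_steps=relax_steps, dt=2e-4,
                               sample_every=relax_steps,
                               seed=int(rng.integers(2**31))),
                      check_topology=False).frame(-1)
        sys_ = PolymerSystem(chains=settled.chains, extra_bonds=[(0, n)],
                             affinity_pairs=[(q, q + n // 2), (q, n + q)])
    config = ScenarioConfig(kind="tethered_pair", dlk=dlk, epsilon=epsilon,
                            n_copies=2, seed=seed)
    return Scenario(system=sys_, ff=ff, box=None, config=config,
                    contact_pairs={"intra": (q, q + n // 2),
                                   "inter": (q, n + q)},
                    equilibration_multiple=10.0)


def make_separation_sweep(dlk: float, epsilon: float = 8.0,
                          separations_bp: Sequence[float] = (16_000, 200_000, 400_000),
                          seed: int = 0) -> list[Scenario]:
    """One dilute chromatin-loop scenario per enhancer-promoter genomic
    separation (16 kb -> 4 beads, 200 kb -> 50, 400 kb -> 100)."""
    out = []
    for s_bp in separations_bp:
        beads = bp_to_beads(s_bp, CHROMATIN_BP_PER_BEAD)
        out.append(chromatin_loop(dlk, epsilon, separation_beads=beads, seed=seed))
    return out


# ---------------------------------------------------------------------------
# validation telegraph + unit conversions
# ---------------------------------------------------------------------------

def make_markov_telegraph(k_on: float, k_off: float, duration: float,
                          sample_dt: float, seed: int = 0,
                          return_events: bool = False):
    """Exact two-state Markov telegraph sampled on a uniform grid.

    ``k_on`` is the off->on rate, ``k_off`` the on->off rate; the
    stationary fraction-on is k_on / (k_on + k_off), mean dwell times are
    1/k_off (on) and 1/k_on (off).  The continuous-time jump process is
    simulated exactly (exponential waiting times) and then sampled every
    ``sample_dt``; with ``return_events`` the exact (uncensored) on and off
    dwell durations are returned alongside the signal for estimator
    validation.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    n = int(duration / sample_dt)
    samples = np.empty(n, dtype=bool)
    # start from stationarity
    state = bool(rng.random() < k_on / (k_on + k_off))
    dwell = rng.exponential(1.0 / (k_off if state else k_on))
    t_next = dwell
    on_durs, off_durs = [], []
    t = 0.0
    horizon = n * sample_dt
    for i in range(n):
        while t_next <= t:
            if t_next <= horizon:
                (on_durs if state else off_durs).append(dwell)
            state = not state
            dwell = rng.exponential(1.0 / (k_off if state else k_on))
            t_next += dwell
        samples[i] = state
        t += sample_dt
    signal = TelegraphSignal(samples=samples, sample_dt=sample_dt,
                             label=f"markov(k_on={k_on}, k_off={k_off})")
    if return_events:
        return signal, np.array(on_durs), np.array(off_durs)
    return signal


def sample_open_wlc(n: int, k_bend: float, seed: int = 0) -> BeadChain:
    """Exact equilibrium draw of an open discrete worm-like chain.

    Bend angles are sampled directly from the Boltzmann density
    ``exp(k cos(beta))`` (inverse-CDF on cos(beta)), azimuths uniformly;
    bonds at rest length.  Used to initialise persistence-length runs in
    equilibrium — a closed ring started from a circle crumples only on the
    Rouse time, far beyond desk-scale equilibration.
    """
    rng = np.random.default_rng(seed)
    t = np.zeros((n - 1, 3))
    t[0] = (0.0, 0.0, 1.0)
    for i in range(1, n - 1):
        u = rng.random()
        c = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * k_bend)) / k_bend
        c = min(1.0, max(-1.0, c))
        s_ = np.sqrt(1.0 - c * c)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        # local frame about the previous tangent
        a = np.array([0.0, 0.0, 1.0]) if abs(t[i - 1][2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(t[i - 1], a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t[i - 1], e1)
        t[i] = c * t[i - 1] + s_ * (np.cos(phi) * e1 + np.sin(phi) * e2)
    pos = np.concatenate([[np.zeros(3)], np.cumsum(t, axis=0)])
    return BeadChain(positions=pos, closed=False)


def bp_to_beads(bp: float, bp_per_bead: float) -> int:
    """Nearest-integer bead count for a genomic length."""
    if bp < 0 or bp_per_bead <= 0:
        raise ValueError("lengths must be positive")
    return int(round(bp / bp_per_bead))


def kBT_to_kcal(x_kbt: float, temperature: float = 300.0) -> float:
    """Thermal energies to kcal/mol at the given temperature."""
    if x_kbt < 0 or temperature <= 0:
        raise ValueError("invalid input")
    kbt_kcal_mol = Boltzmann * temperature * Avogadro / (calorie * 1000.0)
    return x_kbt * kbt_kcal_mol
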