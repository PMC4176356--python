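"""Overdamped Brownian dynamics of twistable bead chains.

Reduced units throughout: bead diameter d = 1, thermal energy k_B T = 1,
translational bead drag gamma = 1, so time is measured in d^2 gamma / k_B T.
Frame angles carry a rotational drag gamma_r = gamma d^2 / 3 (order of
magnitude of a bead-sized cylinder); only equilibrium observables are
insensitive to this choice, kinetic prefactors are not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _geometry as geom
from . import _kernels as K
from .chain import BeadChain, ForceField, PolymerSystem, as_system

__all__ = [
    "SimulationBox",
    "Schedule",
    "Trajectory",
    "BDIntegrationError",
    "bd_step",
    "run",
    "estimate_equilibration",
]

log = logging.getLogger("twistloop")


class BDIntegrationError(RuntimeError):
    """Raised when the integrator produced non-finite coordinates."""

    def __init__(self, message: str, last_frame: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_frame = last_frame


@dataclass
class SimulationBox:
    """Cubic periodic box (edge in d units) or unbounded dilute space."""

    edge_length: float | None = None
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.periodic:
            if self.edge_length is None or self.edge_length <= 4.0:
                raise ValueError("periodic box edge must exceed 4 bead diameters")

    @property
    def kernel_edge(self) -> float:
        return float(self.edge_length) if self.periodic else -1.0

    def volume(self) -> float:
        if not self.periodic:
            raise ValueError("unbounded box has no volume")
        return float(self.edge_length) ** 3


@dataclass
class Schedule:
    """Integration and sampling protocol.

    ``sample_every`` defaults to 1000 steps; ``equilibration_multiple`` is the
    required ratio of run length to the measured equilibration time (40 for
    DNA-like, 10 for chromatin-like systems).
    """

    n_steps: int
    dt: float = 5e-4
    sample_every: int = 1000
    seed: int = 0
    equilibration_multiple: float = 40.0
    kT: float = 1.0
    gamma: float = 1.0
    gamma_r: float = 1.0 / 3.0
    force_cap: float = 500.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 0 or self.sample_every < 1:
            raise ValueError("invalid schedule")


@dataclass
class Trajectory:
    """Uniformly sampled frames of a multi-ring system.

    ``positions`` are unwrapped even under periodic boundaries;
    ``twists[f, lo:hi]`` hold per-junction material twists of ring r with
    ``lo, hi = ring_start[r], ring_start[r+1]`` (tail entries unused for
    open validation chains).
    """

    times: np.ndarray            # (S,)
    positions: np.ndarray        # (S, M, 3)
    twists: np.ndarray           # (S, M)
    ring_start: np.ndarray
    template: PolymerSystem
    box: SimulationBox
    metadata: dict = field(default_factory=dict)
    burn_index: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_rings(self) -> int:
        return len(self.ring_start) - 1

    def ring_positions(self, ring: int = 0, equilibrated: bool = False) -> np.ndarray:
        lo, hi = self.ring_start[ring], self.ring_start[ring + 1]
        start = self.burn_index if equilibrated else 0
        return self.positions[start:, lo:hi]

    def ring_twists(self, ring: int = 0, equilibrated: bool = False) -> np.ndarray:
        lo, hi = self.ring_start[ring], self.ring_start[ring + 1]
        start = self.burn_index if equilibrated else 0
        return self.twists[start:, lo:hi]

    def frame(self, f: int) -> PolymerSystem:
        chains = []
        for r, tmpl in enumerate(self.template.chains):
            lo, hi = self.ring_start[r], self.ring_start[r + 1]
            chains.append(
                BeadChain(
                    positions=self.positions[f, lo:hi].copy(),
                    twist_angles=self.twists[f, lo:hi].copy(),
                    bead_diameter_nm=tmpl.bead_diameter_nm,
                    bp_per_bead=tmpl.bp_per_bead,
                    special_sites=dict(tmpl.special_sites),
                    closed=tmpl.closed,
                )
            )
        return PolymerSystem(chains=chains,
                             extra_bonds=list(self.template.extra_bonds),
                             affinity_pairs=list(self.template.affinity_pairs))

    def site_distance_series(self, a: int, b: int) -> np.ndarray:
        """Centre-to-centre distances between global bead indices a, b
        (minimum image under periodic boundaries)."""
        dx = self.positions[:, b] - self.positions[:, a]
        if self.box.periodic:
            L = self.box.edge_length
            dx = dx - L * np.round(dx / L)
        return np.linalg.norm(dx, axis=1)


# ---------------------------------------------------------------------------

def _kernel_arrays(system: PolymerSystem):
    """Flatten a system into the kernel's state arrays."""
    pos, theta, dirA, dirT = [], [], [], []
    closed_flags = []
    for ch in system.chains:
        n = ch.n_beads
        p = np.ascontiguousarray(ch.positions, dtype=float)
        pos.append(p)
        if n >= 3 and ch.closed:
            a = geom.bishop_frames(p)
            th = geom.theta_from_junction_twists(p, ch.twist_angles, a, tol=0.5)
            t = geom.ring_tangents(p)
            closed_flags.append(1)
        else:
            # open validation chains (free bead, dimer, bending unit)
            a = np.tile(np.array([[0.0, 0.0, 1.0]]), (n, 1))
            th = np.zeros(n)
            t = np.tile(np.array([[1.0, 0.0, 0.0]]), (n, 1))
            if n >= 2:
                e = np.diff(p, axis=0)
                e = e / np.linalg.norm(e, axis=1, keepdims=True)
                t[: n - 1] = e
                for i in range(n - 1):
                    probe = np.array([0.0, 0.0, 1.0]) if abs(e[i, 2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                    v = np.cross(e[i], probe)
                    a[i] = v / np.linalg.norm(v)
            closed_flags.append(0)
        theta.append(th)
        dirA.append(a)
        dirT.append(t)
    return (
        np.concatenate(pos),
        np.concatenate(theta),
        np.concatenate(dirA),
        np.concatenate(dirT),
        system.offsets.astype(np.int64),
        np.array(closed_flags, dtype=np.uint8),
        np.array(system.extra_bonds, dtype=np.int64).reshape(-1, 2),
        np.array(system.affinity_pairs, dtype=np.int64).reshape(-1, 2),
    )


def _radius_of_gyration(frames: np.ndarray) -> np.ndarray:
    com = frames.mean(axis=1, keepdims=True)
    return np.sqrt(((frames - com) ** 2).sum(axis=2).mean(axis=1))


def run(
    initial: BeadChain | PolymerSystem,
    ff: ForceField,
    box: SimulationBox | None,
    schedule: Schedule,
    scenario_id: str | None = None,
    check_topology: bool = True,
    max_dt_halvings: int = 2,
) -> Trajectory:
    """Propagate and sample; frames before the detected equilibration point
    are flagged via ``Trajectory.burn_index`` (and skipped by analysis
    helpers when ``equilibrated=True``).

    Identical (initial state, schedule seed) yield bit-identical
    trajectories on a given platform.

    For torsionally stressed closed rings the linking number Lk = Tw + Wr
    of the first ring is monitored across the sampled frames; a drift above
    0.05 turns (strand crossing or twist-branch loss) rejects the run and
    retries with a halved timestep, raising after ``max_dt_halvings``.
    """
    system = as_system(initial)
    box = box or SimulationBox()
    pos, theta, dirA, dirT, ring_start, ring_closed, xb, ap = _kernel_arrays(system)
    m = len(pos)
    phi0 = np.concatenate([ff.phi0_array(c.n_beads) for c in system.chains])
    n_samples = schedule.n_steps // schedule.sample_every + 1
    out_pos = np.empty((n_samples, m, 3))
    out_phi = np.empty((n_samples, m))
    out_t = np.empty(n_samples)

    # standard normals are drawn chunk-wise with numpy's PCG64 (fast bulk
    # generation); the kernel consumes them deterministically
    rng = np.random.Generator(np.random.PCG64(schedule.seed & 0x7FFFFFFF))
    ring_of, loc, ring_n, aff_flag = K.bd_init(pos, ap, ring_start)
    ia = np.empty(m * 64, dtype=np.int64)
    ja = np.empty(m * 64, dtype=np.int64)
    pos_ref = np.empty_like(pos)
    chunk = 512
    npairs = 0
    ns = 0
    step0 = 0
    status = K.STATUS_OK
    while True:
        todo = min(chunk, schedule.n_steps - step0)
        noise = rng.standard_normal((todo, 4 * m))
        status, npairs, ns, done = K.bd_chunk(
            pos, theta, dirA, dirT, ring_start, ring_closed, xb, ap, phi0,
            ff.k_bond, ff.rest_length, ff.k_bend, ff.k_dihedral,
            ff.eps_excluded, ff.sigma_lj, ff.epsilon, ff.r_cut,
            box.kernel_edge, schedule.dt, schedule.gamma, schedule.gamma_r,
            schedule.kT, noise, step0, schedule.sample_every,
            schedule.force_cap, ring_of, loc, ring_n, aff_flag,
            ia, ja, npairs, pos_ref, out_pos, out_phi, out_t, ns,
        )
        if status != K.STATUS_OK:
            break
        step0 += todo
        if step0 >= schedule.n_steps:
            break
    if status == K.STATUS_NONFINITE:
        raise BDIntegrationError(
            f"non-finite coordinates after {ns} samples (dt too large or "
            "overlapping initial state); last finite frame attached",
            last_frame=out_pos[max(ns - 1, 0)],
        )
    if status == K.STATUS_OVERFLOW:
        raise BDIntegrationError("neighbour list capacity exceeded")

    traj = Trajectory(
        times=out_t[:ns].copy(),
        positions=out_pos[:ns],
        twists=out_phi[:ns],
        ring_start=ring_start,
        template=system,
        box=box,
        metadata={
            "seed": schedule.seed,
            "dt": schedule.dt,
            "n_steps": schedule.n_steps,
            "sample_every": schedule.sample_every,
            "scenario_id": scenario_id,
            "force_field": {
                "k_bond": ff.k_bond, "k_bend": ff.k_bend,
                "k_dihedral": ff.k_dihedral, "epsilon": ff.epsilon,
                "sigma_lj": ff.sigma_lj, "r_cut": ff.r_cut,
            },
            "gamma": schedule.gamma, "gamma_r": schedule.gamma_r,
        },
    )
    _detect_equilibration(traj, schedule)
    drift = traj.metadata.get("lk_drift")
    if check_topology and drift is not None and drift > 0.05:
        if max_dt_halvings <= 0:
            raise BDIntegrationError(
                f"linking-number drift {drift:.3f} turns exceeds 0.05 even at "
                f"dt = {schedule.dt:g}; run rejected"
            )
        log.warning(
            "Lk drift %.3f turns at dt=%g: topology check failed, halving dt",
            drift, schedule.dt,
        )
        from dataclasses import replace as _replace

        retry = _replace(schedule, dt=schedule.dt / 2.0,
                         n_steps=schedule.n_steps * 2,
                         sample_every=schedule.sample_every * 2)
        return run(initial, ff, box, retry, scenario_id,
                   check_topology, max_dt_halvings - 1)
    return traj


def _detect_equilibration(traj: Trajectory, schedule: Schedule) -> None:
    """Burn-in from the integrated autocorrelation time of the slowest
    tracked observable: writhe for torsionally stressed rings, radius of
    gyration otherwise."""
    if traj.n_frames < 100 or traj.ring_start[1] - traj.ring_start[0] < 6:
        traj.metadata["tau_samples"] = None
        return
    lo, hi = traj.ring_start[0], traj.ring_start[1]
    twisted = np.abs(traj.twists[0, lo:hi]).sum() > 0.1
    frames = traj.ring_positions(0)
    if twisted:
        series = K.writhe_series(np.ascontiguousarray(frames))
        lk = series + traj.ring_twists(0).sum(axis=1) / (2.0 * np.pi)
        traj.metadata["lk_drift"] = float(np.abs(lk - lk[0]).max())
    else:
        series = _radius_of_gyration(frames)
    dt_sample = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    tau = estimate_equilibration(series, dt_sample)
    traj.metadata["observable"] = "writhe" if twisted else "rg"
    if not np.isfinite(tau):
        traj.metadata["tau_samples"] = None
        traj.metadata["equilibrated"] = False
        traj.burn_index = min(traj.n_frames // 5, traj.n_frames - 1)
        return
    tau_samples = tau / dt_sample
    traj.metadata["tau_samples"] = float(tau_samples)
    run_time = traj.times[-1] - traj.times[0]
    traj.metadata["equilibrated"] = bool(
        run_time >= schedule.equilibration_multiple * tau
    )
    traj.burn_index = int(min(np.ceil(5.0 * tau_samples), traj.n_frames - 1))


def bd_step(
    state: BeadChain | PolymerSystem,
    ff: ForceField,
    box: SimulationBox | None,
    dt: float,
    seed: int,
    n_steps: int = 1,
    kT: float = 1.0,
) -> PolymerSystem:
    """A few explicit Euler-Maruyama updates, returned as a new system.

    Deterministic in (state, seed); ``kT = 0`` switches the noise off, so a
    mechanical-equilibrium state stays put.  This is the slow per-call
    interface; long runs should use :func:`run`.
    """
    sched = Schedule(n_steps=n_steps, dt=dt, sample_every=max(n_steps, 1),
                     seed=seed, kT=kT)
    traj = run(state, ff, box, sched, check_topology=False)
    return traj.frame(traj.n_frames - 1)


def estimate_equilibration(series: np.ndarray, dt_sample: float = 1.0) -> float:
    """Integrated autocorrelation time of a scalar series, in time units.

    Uses tau = (1 + 2 sum rho_k) * dt_sample with Sokal's adaptive window
    (smallest W with W >= 5 tau); an i.i.d. series gives one sampling
    interval.  Returns ``inf`` when the estimate does not converge
    (tau > length / 10, or a constant series), which flags the series as
    unequilibrated.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples to estimate equilibration")
    x = x - x.mean()
    var = np.dot(x, x) / len(x)
    if var < 1e-300:
        return np.inf
    n = len(x)
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real
    acf /= acf[0]
    tau = 1.0
    for w in range(1, n // 2):
        tau = 1.0 + 2.0 * np.sum(acf[1 : w + 1])
        if w >= 5.0 * tau:
            break
    else:
        return np.inf
    if tau > n / 10.0 or tau <= 0:
        return np.inf
    return float(tau * dt_sample)
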