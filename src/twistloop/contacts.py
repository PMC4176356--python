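"""Contact telegraph signals and dwell-time statistics.

Two sites are "in contact" when their centre-to-centre distance is below
two bead diameters (surface-to-surface below one diameter), the criterion
used for all contact statistics here.  A trajectory is reduced to a binary
on/off telegraph at the sampling interval; dwell statistics follow from
run-length encoding with the standard censoring convention: the first and
last runs touch the observation window boundaries, so they are excluded
from mean dwell times but still count toward the fraction of time on.

Error bars on telegraph statistics use a moving-block bootstrap with block
length tied to the signal's integrated autocorrelation time, since
successive samples are strongly correlated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dynamics import Trajectory, estimate_equilibration

__all__ = [
    "TelegraphSignal",
    "DwellStats",
    "telegraph",
    "dwell_stats",
    "censored_dwell_mle",
    "enhancement_index",
    "preference_ratio",
    "phase_diagram",
    "PhaseDiagram",
]

CONTACT_THRESHOLD = 2.0  # centre-to-centre, bead diameters


@dataclass
class TelegraphSignal:
    """Binary contact time series at a fixed sampling interval."""

    samples: np.ndarray       # bool
    sample_dt: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=bool)
        if self.sample_dt <= 0:
            raise ValueError("sampling interval must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) * self.sample_dt

    def runs(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, lengths) run-length encoding."""
        x = self.samples
        if len(x) == 0:
            return np.empty(0, bool), np.empty(0, int)
        edges = np.flatnonzero(np.diff(x)) + 1
        starts = np.concatenate([[0], edges])
        lengths = np.diff(np.concatenate([starts, [len(x)]]))
        return x[starts], lengths


@dataclass
class DwellStats:
    """Fraction-on and censoring-corrected mean dwell times.

    ``mean_t_on`` / ``mean_t_off`` are ``nan`` (flagged, not fabricated)
    when no interior (uncensored) run of that state exists.  Durations are
    in the trajectory's reduced time units.
    """

    fraction_on: float
    mean_t_on: float
    mean_t_off: float
    median_t_on: float
    median_t_off: float
    n_on_events: int
    n_off_events: int
    fraction_on_ci: tuple[float, float]
    mean_t_on_ci: tuple[float, float] = (np.nan, np.nan)
    mean_t_off_ci: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_on <= 1.0):
            raise ValueError("fraction_on outside [0, 1]")


def telegraph(traj: Trajectory, site_a: int, site_b: int,
              threshold: float = CONTACT_THRESHOLD,
              equilibrated: bool = True) -> TelegraphSignal:
    """Contact telegraph between two beads (global indices).

    ``threshold`` is the centre-to-centre distance in bead diameters
    (default 2 d = 6 nm for 3 nm beads); periodic boxes use minimum-image
    distances.
    """
    m = traj.positions.shape[1]
    if not (0 <= site_a < m and 0 <= site_b < m):
        raise KeyError("contact site index outside the system")
    if threshold <= 1.0:
        raise ValueError("contact threshold must exceed one bead diameter")
    d = traj.site_distance_series(site_a, site_b)
    if equilibrated:
        d = d[traj.burn_index:]
    if traj.n_frames > 1:
        dt = float(traj.times[1] - traj.times[0])
    else:
        dt = 1.0
    return TelegraphSignal(samples=d < threshold, sample_dt=dt,
                           label=f"{site_a}-{site_b}")


def _block_ci(x: np.ndarray, dt: float, stat: Callable, n_boot: int = 200,
              seed: int = 0) -> tuple[float, float]:
    n = len(x)
    if n < 10:
        return (np.nan, np.nan)
    try:
        tau = estimate_equilibration(x.astype(float), dt)
        block = int(min(max(5.0 * tau / dt, 1), n // 2))
    except (ValueError, OverflowError):
        block = max(n // 20, 1)
    if not np.isfinite(block) or block < 1:
        block = max(n // 20, 1)
    rng = np.random.default_rng(seed)
    n_blocks = max(n // block, 1)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        sample = np.concatenate([x[s:s + block] for s in starts])
        vals[b] = stat(sample)
    return float(np.quantile(vals, 0.025)), float(np.quantile(vals, 0.975))


def dwell_stats(signal: TelegraphSignal, n_boot: int = 200, seed: int = 0) -> DwellStats:
    """Run-length statistics of a telegraph signal.

    fraction_on is the exact ratio of on-samples to all samples (censored
    boundary runs included); mean dwell times use interior runs only.
    Heavy-tailed off-times are reported as-is, with medians alongside means.
    """
    if len(signal) < 2:
        raise ValueError("telegraph too short")
    vals, lens = signal.runs()
    frac = float(np.mean(signal.samples))
    # interior runs: drop the first and last (censored at the boundaries)
    iv, il = vals[1:-1], lens[1:-1]
    t_on = il[iv] * signal.sample_dt
    t_off = il[~iv] * signal.sample_dt
    x = signal.samples.astype(float)
    frac_ci = _block_ci(x, signal.sample_dt, np.mean, n_boot=n_boot, seed=seed)

    def _mean_ci(durs: np.ndarray) -> tuple[float, float]:
        if len(durs) < 3:
            return (np.nan, np.nan)
        rng = np.random.default_rng(seed + 1)
        vals_ = np.array([
            np.mean(rng.choice(durs, size=len(durs))) for _ in range(n_boot)
        ])
        return float(np.quantile(vals_, 0.025)), float(np.quantile(vals_, 0.975))

    return DwellStats(
        fraction_on=frac,
        mean_t_on=float(np.mean(t_on)) if len(t_on) else np.nan,
        mean_t_off=float(np.mean(t_off)) if len(t_off) else np.nan,
        median_t_on=float(np.median(t_on)) if len(t_on) else np.nan,
        median_t_off=float(np.median(t_off)) if len(t_off) else np.nan,
        n_on_events=int(len(t_on)),
        n_off_events=int(len(t_off)),
        fraction_on_ci=frac_ci,
        mean_t_on_ci=_mean_ci(t_on),
        mean_t_off_ci=_mean_ci(t_off),
    )


def censored_dwell_mle(signals) -> dict:
    """Censoring-corrected dwell means and renewal occupancy from one or
    more telegraph signals.

    For (approximately) exponential dwells, the maximum-likelihood mean in
    the presence of right/left censoring at the observation windows is the
    total time spent in a state divided by the number of observed
    departures from it.  The renewal estimate of the stationary occupancy
    is then ``t_on / (t_on + t_off)``.  This is far more stable than
    interior-run means when dwells are comparable to the run length (the
    long excursions are censored and would otherwise be dropped), and it
    pools runs started in different states coherently.

    With zero observed departures the corresponding mean is a lower bound
    (total time / 1) and is flagged via the transition counts.
    """
    if isinstance(signals, TelegraphSignal):
        signals = [signals]
    total_on = total_off = 0.0
    dep_on = dep_off = 0
    for sig in signals:
        x = sig.samples
        total_on += float(x.sum()) * sig.sample_dt
        total_off += float((~x).sum()) * sig.sample_dt
        dep_on += int(np.sum(x[:-1] & ~x[1:]))    # on -> off switches
        dep_off += int(np.sum(~x[:-1] & x[1:]))   # off -> on switches
    t_on = total_on / max(dep_on, 1)
    t_off = total_off / max(dep_off, 1)
    denom = t_on + t_off
    return {
        "mean_t_on": t_on,
        "mean_t_off": t_off,
        "n_on_departures": dep_on,
        "n_off_departures": dep_off,
        "occupancy": t_on / denom if denom > 0 else np.nan,
    }


def _ratio_with_ci(num: DwellStats, den: DwellStats) -> tuple[float, tuple[float, float]]:
    r = num.fraction_on / den.fraction_on
    lo = num.fraction_on_ci[0] / den.fraction_on_ci[1] if den.fraction_on_ci[1] else np.nan
    hi = num.fraction_on_ci[1] / den.fraction_on_ci[0] if den.fraction_on_ci[0] else np.inf
    return float(r), (float(lo), float(hi))


def enhancement_index(stats_at_dlk: DwellStats, stats_at_zero: DwellStats):
    """Fold change of fraction-on at a given dLk relative to dLk = 0.

    Returns (fold, (ci_low, ci_high)); raises when the reference
    fraction-on is zero (the index is then undefined).
    """
    if stats_at_zero.fraction_on <= 0:
        raise ZeroDivisionError("reference fraction_on is zero; index undefined")
    return _ratio_with_ci(stats_at_dlk, stats_at_zero)


def preference_ratio(stats_intra: DwellStats, stats_inter: DwellStats,
                     n_samples: int | None = None):
    """Intra- vs inter-domain preference of an enhancer for two equidistant,
    equally attractive promoters.

    The two telegraphs are tracked independently (the enhancer may contact
    both promoters simultaneously).  When the inter-domain telegraph shows
    no on-time at all, the ratio is reported as a lower bound: the
    denominator is replaced by the upper edge of its bootstrap CI, or by a
    rule-of-three bound 3/n_eff when even that is zero.  Returns
    (ratio, (ci_low, ci_high), is_lower_bound).
    """
    if stats_inter.fraction_on > 0:
        r, ci = _ratio_with_ci(stats_intra, stats_inter)
        return r, ci, False
    floor = stats_inter.fraction_on_ci[1]
    if not np.isfinite(floor) or floor <= 0:
        if not n_samples:
            raise ZeroDivisionError(
                "inter-domain fraction_on is zero and no sample size given"
            )
        floor = 3.0 / n_samples
    bound = stats_intra.fraction_on / floor
    return float(bound), (float(stats_intra.fraction_on_ci[0] / floor), np.inf), True


# ---------------------------------------------------------------------------
# phase diagram over (dLk, epsilon)
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Cubic-interpolated fraction-on surface with isoprobability lines."""

    dlk_values: np.ndarray
    eps_values: np.ndarray
    fraction_on: np.ndarray            # (n_dlk, n_eps), nan = missing
    dlk_fine: np.ndarray = field(default=None)
    eps_fine: np.ndarray = field(default=None)
    surface: np.ndarray = field(default=None)
    isolines: dict = field(default_factory=dict)


def phase_diagram(dlk_values, eps_values, fraction_on,
                  levels=(0.1, 0.25, 0.5, 0.75), refine: int = 64) -> PhaseDiagram:
    """Interpolate a fraction-on grid over (dLk, epsilon) and extract
    isoprobability lines.

    Complete grids use bicubic spline interpolation; grids with missing
    (nan) cells fall back to scattered cubic interpolation clipped to the
    data hull, and isolines are truncated at the mask edge.  Isoline
    vertices are returned in data coordinates as (dlk, eps) arrays.
    """
    from skimage.measure import find_contours

    dlk_values = np.asarray(dlk_values, float)
    eps_values = np.asarray(eps_values, float)
    z = np.asarray(fraction_on, float)
    if z.shape != (len(dlk_values), len(eps_values)):
        raise ValueError("grid shape mismatch")
    if len(dlk_values) < 2 or len(eps_values) < 2:
        raise ValueError("need at least a 2x2 grid")
    order = np.argsort(dlk_values)
    dlk_values, z = dlk_values[order], z[order]
    order = np.argsort(eps_values)
    eps_values, z = eps_values[order], z[:, order]

    xf = np.linspace(dlk_values[0], dlk_values[-1], refine)
    yf = np.linspace(eps_values[0], eps_values[-1], refine)
    if not np.any(np.isnan(z)):
        from scipy.interpolate import RectBivariateSpline

        kx = min(3, len(dlk_values) - 1)
        ky = min(3, len(eps_values) - 1)
        spl = RectBivariateSpline(dlk_values, eps_values, z, kx=kx, ky=ky)
        surf = spl(xf, yf)
    else:
        from scipy.interpolate import griddata

        pts, vals = [], []
        for i, x in enumerate(dlk_values):
            for j, y in enumerate(eps_values):
                if np.isfinite(z[i, j]):
                    pts.append((x, y))
                    vals.append(z[i, j])
        gx, gy = np.meshgrid(xf, yf, indexing="ij")
        surf = griddata(pts, vals, (gx, gy), method="cubic")

    iso = {}
    for lev in levels:
        paths = []
        for contour in find_contours(np.where(np.isfinite(surf), surf, np.nan), lev):
            ii, jj = contour[:, 0], contour[:, 1]
            x = np.interp(ii, np.arange(refine), xf)
            y = np.interp(jj, np.arange(refine), yf)
            paths.append(np.column_stack([x, y]))
        iso[lev] = paths
    return PhaseDiagram(dlk_values=dlk_values, eps_values=eps_values,
                        fraction_on=z, dlk_fine=xf, eps_fine=yf,
                        surface=surf, isolines=iso)
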