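# Methods

`twistloop` simulates closed, torsionally stressed bead-spring polymers —
supercoiled DNA plasmids and 30 nm chromatin-fibre loops — and measures how
supercoiling and site–site affinity jointly control the contact statistics
of two designated beads (an "enhancer" and a "promoter"). This note records
the model, the estimators, the numerical choices, and what the desk-scale
test suite does and does not demonstrate.

## Model

A molecule is a closed ring of `N` beads of diameter `d` (3 nm for DNA,
30 nm for chromatin). Reduced units: `d = 1`, `k_B T = 1`, bead drag
`γ = 1`; the time unit is `d²γ/k_BT`. Energy terms:

| term | form | parameters |
|------|------|------------|
| bond | `½ k_bond (b − 1)²` | `k_bond = 200 k_BT/d²` (≈7% length fluctuation) |
| bending | `k_bend (1 − cos β)` | `k_bend` from the persistence length (below) |
| torsion | `½ k_tor (1 − cos(φ − φ₀))` | `k_tor = 65 k_BT` (DNA), `50 k_BT` (chromatin) |
| excluded volume | WCA (shifted-truncated 12-6), cut `2^{1/6} d` | `ε_ev = 1 k_BT` |
| affinity | plain-truncated 12-6, cut `2 d` | well depth `ε ∈ [0, 12] k_BT`, enhancer–promoter pairs only |

The affinity well is truncated but *not* shifted (its minimum is exactly
`−ε` and it vanishes identically beyond the cut, at the price of a `0.06 ε`
discontinuity there) — the convention of the simulation engines this model
family comes from.

**Bending stiffness from persistence length.** For `E = k (1 − cos β)` the
discrete-chain tangent correlation is `⟨cos β⟩ = coth k − 1/k`; we set `k`
by inverting `⟨cos β⟩ = exp(−l/P)` exactly rather than using the
first-order `k = P/l`. For DNA (`P` = 17 bonds) the two differ by 3%
(`k ≈ 17.5`) and excluded volume barely perturbs the stiff chain, so the
analytic value recovers 51 nm in simulation. The floppy chromatin fibre
(`P` = 60 nm = 2 bonds) is different: next-nearest-bead excluded volume
suppresses sharp bends and renormalises the apparent stiffness, so the
bare inversion (`k ≈ 2.44`) yields an effective persistence length of
~70 nm. The chromatin bending constant is therefore *calibrated* —
`k_bend = 1.90` gives an effective 60 nm within a few percent — in the
same spirit as the torsional-stiffness calibration. The calibration used
an exact Boltzmann sampler for the open discrete WLC (sequential
inverse-CDF draws of the bend angles), which doubles as an equilibrium
initial-state generator and as an independent check that the integrator
preserves the bending ensemble it is handed.

**Twist representation.** Each segment carries a reference director that is
parallel-transported *in time* (the minimal rotation taking the old tangent
to the new one, applied every step) and a frame angle `θ` measured against
it; the material twist at a junction is the signed angle between the
transported material director of one segment and that of the next, about
the downstream tangent — the mid-segment frame-transport scheme, exact to
first order in the bending angle and well defined at 90° bends. This is the
discrete-elastic-rod construction: writhe picked up by the centre line
appears in the junction twists with the opposite sign automatically, so

    Lk = Tw + Wr

is conserved *by construction* up to integration error. Measured drift over
2·10⁶ steps is below 10⁻³ turns; a drift above 0.05 turns (a strand
crossing through the soft excluded volume, or a twist-branch loss) rejects
the run, and the driver retries with a halved timestep.

The positional force from torsion goes through the curvature binormal
`kb = 2 e₁×e₂ /(|e₁||e₂| + e₁·e₂)`, with `∂φ/∂e₁ = kb/2|e₁|`,
`∂φ/∂e₂ = kb/2|e₂|`; frame torques are `−∂E/∂θ`. All analytic gradients
are pinned against central finite differences of the energy (relative
error < 10⁻⁵) and the compiled kernel against a plain numpy reference
implementation (agreement to rounding).

**Imposing ΔLk.** A ring built flat with uniform junction twists summing to
`2π·ΔLk` has `Lk = Tw + Wr = ΔLk` exactly at frame zero; dynamics then
partitions the linking difference between residual twist and writhe. (An
equivalent equilibrium-offset mechanism, `φ₀ = 2π·ΔLk/N`, is supported in
the force field; the initial-twist form keeps the sign convention that
negative ΔLk yields negative writhe.) The model is mirror-symmetric: only
`|ΔLk|` matters physically, signs are bookkeeping.

## Dynamics

Overdamped Euler–Maruyama: `Δx = F dt/γ + √(2 k_BT dt/γ) ξ`, and likewise
for the frame angles with rotational drag `γ_r = γ d²/3` (order of
magnitude for a bead-sized cylinder; only equilibrium observables are used
for quantitative targets, so the exact value affects time scales, not
averages). Default `dt = 5·10⁻⁴` reduced time, validated by the
Lk-conservation guard above; pair forces are capped at 500 `k_BT/d` to tame
the rare deep-core WCA spike (visited with Boltzmann weight `e^{−20}`;
bond-length statistics are unaffected). Non-bonded pairs come from a cell
list with a 0.45 `d` Verlet skin, rebuilt when any bead has moved half a
skin; results are identical to the all-pairs computation. Configurations
are sampled every 1000 steps.

Thermostat correctness is tested directly: free-bead MSD against the
Einstein relation, dimer bond-length variance against `k_BT/k_bond`, and
the bend-angle distribution of a three-bead unit against
`exp(−k(1−cos β)) sin β` (KS test).

**Equilibration.** The integrated autocorrelation time τ of the slowest
tracked observable (writhe for supercoiled rings, radius of gyration
otherwise) is estimated with Sokal's adaptive window, with the convention
τ = 1 sampling interval for white noise. Burn-in is 5τ; a run is flagged
unequilibrated if τ does not converge (τ > length/10) or the run is shorter
than 40τ (DNA) / 10τ (chromatin).

## Topology analysis

Writhe is the exact polygon value: the Gauss double integral evaluated in
closed form as signed solid angles over all non-adjacent segment pairs
(O(N²), exact to rounding; the tests compare it against brute-force double
quadrature on random smooth rings to 10⁻³). Twist is `Σφᵢ/2π` in turns.
Supercoiling density uses a helical repeat of 10.5 bp/turn, consistent
with σ ≈ −0.05 at ΔLk = −15 on 3000 bp.

At ΔLk = −15 (DNA parameterization) the equilibrium mean `⟨|Wr|⟩/|ΔLk|`
measures 0.80–0.84 across seeds (per-run bootstrap CI widths of a few
percent) with the dihedral stiffness at 65 k_BT — no recalibration was
needed. For the chromatin loop at
|ΔLk| = 20 and `k_tor = 50`, `⟨|Wr|⟩ ≈ 18.0`; the acceptance script
contains an upward-calibration loop for the torsional stiffness (raising it
if `⟨|Wr|⟩` falls below 16) that is not triggered under defaults.

`⟨|Wr|⟩` is used rather than `|⟨Wr⟩|`; the sign of Wr is locked to the sign
of ΔLk and no sign flips occur at the supercoiling densities studied.

The persistence length estimator fits `⟨t(0)·t(s)⟩ = exp(−s/P)` over a
window of separations and supports both rings and open chains. Two
pitfalls are handled explicitly: ring closure biases wide-window fits
(the correlation is driven negative near `s = N/2`), so stiff rings use
`s ≲ 0.7 P`; and a ring started from a flat circle only crumples on the
Rouse time, far beyond desk-scale equilibration, so recovery runs start
from exact open-WLC Boltzmann draws and pool several independent replicas
(whole-chain shape modes decorrelate slowly within any single run).

## Contact statistics

Two sites are in contact when their centre-to-centre (minimum-image)
distance is below two bead diameters — 6 nm for 3 nm DNA beads. The
trajectory reduces to a binary telegraph; run-length encoding gives the
fraction-on (all samples, exact ratio) and mean dwell times (interior runs
only; the censored first and last runs are excluded from the means). An
absent state yields a flagged `nan`, never a fabricated number; heavy-tailed
off-times are reported as-is with medians alongside means. Confidence
intervals use a moving-block bootstrap with block length 5× the telegraph's
integrated autocorrelation time; bare dwell means use an ordinary bootstrap
over events. The estimators are validated against exact two-state Markov
telegraphs with known rates (closed forms for fraction-on and mean dwells;
exponential dwell distributions by construction, KS-tested on the exact
event durations).

For conditions where dwell times are comparable to the affordable run
length, interior-run means are unstable (the long excursions are exactly
the censored ones). The censoring-corrected alternative is the
exponential-dwell maximum-likelihood estimate — total time in a state per
observed departure from it — and the renewal occupancy
`t_on/(t_on + t_off)` built from those means; this pools runs started in
different states coherently and is the estimator used for the
enhancement-index measurements.

The enhancement index is the fold change of fraction-on (or renewal
occupancy) relative to ΔLk = 0; the preference ratio is intra- over inter-domain fraction-on for
one enhancer with two equidistant, equally attractive promoters (contacts
tracked independently — simultaneous contact is allowed). When the
inter-domain telegraph shows no on-time at all, the ratio is reported as a
lower bound, dividing by the upper edge of the denominator's bootstrap CI
or, failing that, a rule-of-three bound `3/n_eff` with
`n_eff = samples / (5τ)`.

The (ΔLk, ε) phase surface is interpolated bicubically on the run grid
(default ΔLk ∈ {0, −5, −10, −15, −20} × ε ∈ {0, 4, 8, 10, 12} k_BT);
isoprobability lines at fraction-on {0.1, 0.25, 0.5, 0.75} are extracted
from the refined surface, clipped where grid cells are missing.

## Scenarios and initial conditions

* **Plasmid**: 3000 bp at the B-DNA rise of 0.34 nm/bp → 1020 nm contour →
  340 beads of 3 nm (~8.8 bp/bead), persistence length 17 beads, sites at
  beads 0 and 170 (180° apart on the circular map), ΔLk ∈ [−20, 0].
* **Chromatin loop**: 200 beads × 4000 bp = 800 kb; sites separated by
  4 / 50 / 100 beads for the 16 kb / 200 kb / 400 kb genomic separations.
* **Crowded box**: 20 loop copies in a periodic cube sized so the bead
  volume fraction is exactly 20% (edge ≈ 21.9 d); loops are dropped at
  random positions/orientations and resolved by a force-capped push-off
  plus a settle phase. Excluded volume acts between copies; affinity is
  intra-loop only.
* **Tethered pair**: two loops joined by a single harmonic bond between
  bead 0 of each (the minimal mechanism that keeps the domains
  topologically independent), bodies pointing away from each other along
  the tether direction. E at bead 50 of loop 1; P1 at bead 150 (same loop);
  P2 at bead 50 of loop 2 — both promoters 100 beads (~400 kb) from E,
  P2 measured through the tether.

**Plectonemic starts.** Supercoiled rings start from a constructed
interwound superhelix (two antiparallel helical strands plus semicircular
end caps) whose exact writhe is matched to the expected equilibrium
partition (~0.8·ΔLk for DNA, ~0.9·ΔLk for chromatin) by scanning the turn
number; the residual ΔLk − Wr is stored as uniform twist so the topology is
exact from frame zero. Starting from a flat twisted circle converges to the
same writhe but takes orders of magnitude longer (and, for the floppy
fibre, can cross strands during the violent buckling transient — which the
topology guard catches).

**The slithering phase is an initial condition.** Which contour position
sits at the plectoneme apexes relaxes only by slithering — reptation of the
superhelix along its own contour — which is far slower than any desk-scale
run (this slowness is precisely the mechanism by which supercoiling
shortens `⟨t_off⟩`: dissociated partners stay juxtaposed and rebind). The
generators therefore treat the phase as part of the initial condition:
drawn uniformly by default, or chosen to juxtapose the two sites
(`contact_start=True`). Contact-start runs measure what the dwell-time
analysis needs — how long contacts persist and how quickly they reform —
and are the only honest desk-scale protocol for the stiff plasmid, whose
spontaneous site juxtaposition at ΔLk = 0 is simply unobservable in
minutes of CPU (measured: zero contacts in 600 reduced-time units). The
fraction-on values from contact starts are conditional on starting in the
bound basin and are used for *comparisons across conditions started
identically*, not as absolute equilibrium occupancies. ΔLk = 0 references
additionally pool relaxed-start replicas: at ΔLk = 0 there is no frozen
phase, but the bound and unbound basins still interconvert slowly, so an
even mixture of both starts, reduced through the censoring-corrected
renewal estimator, is the best desk-scale occupancy estimate (bound-start
alone overweights the near basin; relaxed-start alone may never bind
within a run). The residual conditional bias inflates the supercoiled
numerators of the enhancement indices — the proximal (16 kb) index in
particular comes out around 3 at desk scale where converged
phase-averaged statistics give ~1.2 — which is why the proximal claim is
asserted as an ordering (smaller than the distal index), not a magnitude.

## What the desk-scale suite shows — and what it does not

The analytic targets (supercoiling density, bead/bp bookkeeping, k_BT→
kcal/mol) and the equilibrium topology calibrations (writhe fraction ≈ 80%
at ΔLk = −15; chromatin `⟨|Wr|⟩ ≈ 18` at |ΔLk| = 20) are quantitative and
reproduce at full system size in minutes. The contact-statistics claims —
the supercoiling–affinity synergy, the ≥3-fold distal enhancement vs ~1.2
proximal, the intra/inter-domain preference — are reproduced at reduced
statistics: runs of ~10⁵–10⁶ samples fewer than the original production
scale, pooled over a few seeds, asserting directions and magnitude orders
rather than converged values. Inter-domain contacts are often entirely
absent at this scale, in which case only a lower bound on the preference
ratio is reported. Crowded-box (20-copy) production statistics are out of
scope; the crowded generator itself is fully tested (packing, volume
fraction, PBC consistency, short dynamics).

The synthetic systems emulate torsionally stressed, topologically closed
homogeneous polymers. They do not emulate sequence-dependent bending,
nucleosome-scale structure, chirality asymmetry between positive and
negative supercoiling, topoisomerase activity (Lk is strictly conserved),
hydrodynamic interactions, or competing multi-site affinity networks, so
passing tests say nothing about those aspects of real chromatin.

## Numerical details worth knowing

* Timestep 5·10⁻⁴ reduced time; halved automatically (with doubled step
  count) if the Lk guard trips. The push-off phases of the crowded and
  tethered generators use dt 10⁻⁴ with pair forces capped at 50.
* Equal-seed runs are bit-identical on one platform (noise is drawn
  chunk-wise from a PCG64 generator seeded by the schedule seed).
* Bond-length "validity" is statistical: ≤5% of bonds may sit outside
  [0.8, 1.2]·rest (right-skewed thermal tail, slightly inflated by the
  Euler step), hard bounds [0.6, 1.4].
* The junction-twist principal value assumes |φ| < π per junction; at the
  supercoiling densities studied the mean twist per junction is ≤ 0.63 rad
  with fluctuations ~0.15 rad, far from the branch cut.
* Degenerate inputs: zero-length segments raise; antiparallel consecutive
  tangents make the transport ambiguous and raise; constant observable
  series are flagged non-convergent (τ = ∞) rather than silently accepted.
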