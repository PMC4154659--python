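# Methods

## The model

Each *niche lineage* is one haematopoietic stem-cell (HSC) niche
together with all of its descendant cell populations, tracked as six
integer counts: stem cells `S`, multipotent progenitors `MPP`, common
lymphoid and myeloid progenitors `CLP`, `CMP`, and differentiated
lymphoid and myeloid blood cells `L`, `M`.  Fourteen first-order
transitions connect them (see `TransitionTable.to_text()` for the full
table): S divides symmetrically (S+1, capacity-limited), asymmetrically
(MPP+1), or differentiates symmetrically (S−1, MPP+2); MPP multiplies
or commits to one progenitor route; progenitors mature 1:1 into blood
cells; every species dies at a first-order rate.  All rates are per
second; the defaults are the model's canonical set (r_sym=2.5,
r_asym=1, r_sdiff=0.001, r_mpp_ren=0.25, all differentiation rates 0.1,
deaths 0.004/0.02/0.001/0.001/0.028/0.01, K=10).

Blood cells feed back on the primitive compartments:

* `h1 = 1/(1 + b1L·L + b1M·M)` multiplies all S activity,
* `h2` (same form, its own coefficients) additionally multiplies S
  symmetric differentiation,
* `h3` multiplies all MPP activity,
* the multipotent progenitor commitment response (MPCR)
  `p = γ(M′/L′)^θ / (1 + γ(M′/L′)^θ)` is the probability an MPP takes
  the lymphoid route; a zero count is replaced by 1 in the ratio.

These closed forms are the standard Hill-type inhibitions of the prior
feedback-control literature; they satisfy the model's qualitative
requirements (additive effects of L and M, range (0,1], inhibition
deepening with cell numbers, relief as numbers fall, θ=0 a
non-responsive MPCR).  Both are isolated behind `eval_feedback` /
`eval_mpcr` so alternates can be swapped.

Setting `γ = ρ^(θ+1)` pins the MPCR to a target homeostatic ratio
`ρ = L*/M*` independently of the response strength θ
(`calibrate_mpcr`); the defaults use ρ = 0.5, θ = 1, γ = 0.25.  With
unequal L/M death rates the realised steady ratio deviates from ρ
(here L*/M* ≈ 0.30); this is a property of the rate constants, not of
the calibration.

Design choices where the wiring was open: h1 and h2 both multiply
symmetric differentiation (configurable via `h1_on_sdiff`); the
carrying capacity enters only symmetric self-renewal as a logistic
factor `(1 − S/K)`, so K bounds S without throttling output flux;
death transitions carry no feedback; each lineage is founded by a
single stem cell.

## Calibrated feedback coefficients

The feedback coefficients are not part of the canonical rate table, so
the package calibrates its defaults from the mean-field limit
`dx/dt = Σ_j ν_j a_j(x)` (`mean_field_rhs`, `calibrate_feedbacks`).
Two targets define them:

* homeostatic myeloid level `M* ≈ 250` cells per lineage (a few
  hundred, keeping a single lineage cheap to simulate while large
  enough for meaningful distributions);
* homeostatic stem-cell feedback `h1* ≈ 0.003`, which places the
  stem-cell compartment in the near-neutral regime where symmetric
  self-renewal barely balances death.  An exact continuous-time
  Markov-chain computation on the isolated 11-state stem-cell
  birth-death chain (frozen feedbacks) then predicts that individual
  lineages lose their stem cells stochastically — roughly a third by
  t = 1500 s and most by t = 5000 s — while the lineage survives on
  MPP self-renewal, the behaviour the model is meant to exhibit.

Solving both targets gives `b1L = b1M = b2L = b2M = 1.0` and
`b3L = b3M = 0.02` per cell, with mean-field fixed point
`x* ≈ (4.8, 350, 21, 25, 75, 251)` and `h3* ≈ 0.1331`, just below the
MPP self-sufficiency threshold `d_MPP / (r_mpp_ren − r_mpp_diff) ·
(…) ≈ 0.1333` — the MPP pool is a large, slowly relaxing reservoir
stabilised by the h3 feedback, which is what produces the slow
post-perturbation modes.  `nichesim calibrate-feedbacks` re-runs this
calibration for other targets.

## Simulation engine

**Exact SSA.**  Waiting times are exponential with rate `a0 = Σ_j a_j`
and channels chosen with probability `a_j/a0`.  Because each lineage
jumps at its own random times, the SSA is offered for *uncoupled*
lineages only: a pooled feedback field over asynchronous lineages
would average the interactions over time instead of evaluating them
at a common state.

**Synchronised tau-leap.**  The whole metapopulation is one
6 × Ω state matrix.  Per step: propensities of all lineages are
evaluated; the lineage with the largest a0 (the bottleneck) donates
its propensity vector to the step-size rule; every lineage is advanced
over the same τ by independent Poisson counts `K_j ~ Poisson(a_j τ)`.
The step-size rule bounds the mean and standard deviation of each
species' change by `max(ε·x_i, 1)`:
`τ = min_i min( bound_i/|μ_i|, bound_i²/σ_i² )` with
`μ_i = Σ_j ν_ij a_j`, `σ_i² = Σ_j ν_ij² a_j`.  Every transition is
first order in its single reactant, so the highest-order scaling
factor is 1 for all species.  Reaction criticality is deliberately not
handled; negativity is handled by redoing the step with τ/2 and fresh
Poisson draws (up to `max_halvings`, default 30).  A tighter
off-by-default variant (`per_transition_max`) selects the maximum of
each transition's propensity across lineages with the most
conservative per-species bound.

The redo rule is also triggered when a leap overshoots the stem-cell
carrying capacity: the logistic factor only zeroes the propensity *at*
S = K, so a Poisson draw from S < K can exceed K across a finite step.
Treating that like a negative count preserves S ≤ K as an exact
invariant of recorded trajectories.

ε defaults to 0.03 (common values are of order 0.01; 0.1 is fast and
rough, 0.01 accurate), with a τ floor of 1e-6 s against pathological
stalls.  Steps are truncated at record and perturbation times, so
scheduled events occur exactly; a perturbation coinciding with a
record time is applied first.  All dynamics randomness flows from one
seeded PCG64 stream; each perturbation uses its own seeded stream so a
hit pattern can be replayed across group sizes.  Equal seeds and
configuration give bit-identical results.

At the calibrated homeostatic state the accepted step is τ ≈ 0.1–0.4 s
(limited by the small CLP/CMP pools), roughly an order of magnitude
larger than the mean SSA waiting time, with the entire metapopulation
advanced per step.

**Discretisation bias.**  The leap's one-step mean update is
`x(1 − cτ)` against the exact `x e^{−cτ}`, an O(ε) relative bias per
unit time for first-order decay.  Engine tests that compare ensemble
means against closed forms therefore run at ε ≤ 0.005 so the bias sits
well below the Monte-Carlo error; distribution-level accuracy is
judged against the SSA self-distance instead (below).

## Niche-group coupling

Lineages are partitioned into contiguous groups of size n.  The
feedback signals of every member are computed from the group's pooled
blood-cell counts divided by n.  For the linear-in-counts feedbacks
this normalisation is algebraically identical to dividing the
coefficients by n, and it cancels in the MPCR ratio, so one
coefficient set serves all group sizes and the homeostatic state is
independent of n.  Within a group all four signals are identical at
every step; n = 1 reduces bit-for-bit to the uncoupled computation.

## Perturbation protocols

Three removal protocols target the myeloid pool at a scheduled time,
built to remove the same expected fraction (37.5%) of the
metapopulation's M: even (37.5% from every lineage), uneven (75% from
every second lineage, 1-based even positions), random (each lineage
independently loses 75% with probability 0.5).  Removal counts are
`round(f·M)` half-away-from-zero — the protocols state fixed
percentages, so binomial thinning is not used.  Counts never go
negative and non-target species are untouched.

## Analysis

* **Distributions.**  Histograms carry probability mass per bin;
  comparisons use the L1 distance between bin masses on shared edges
  (range [0, 2]).  Shared edges use the Freedman–Diaconis width of the
  pooled samples rounded to an integer ≥ 1.  The noise floor is the
  *self-distance* between two independent SSA ensembles; an
  approximate method is "as accurate as exact" when its distance is
  comparable to that floor.  Distances depend on the binning, which is
  why the edges are shared and configurable.
* **Perturbation response.**  Overshoot is the post-perturbation
  maximum of the ensemble mean *after* it first recovers past the
  steady mean (so the removal dip is not the spike), minus the steady
  mean.  Return time uses a band-and-dwell rule: first entry into
  `steady_mean ± 1 SD` that persists for a 100 s dwell window.  The
  steady mean and SD come from the 1000 s preceding the perturbation:
  the ensemble mean fluctuates with an integrated autocorrelation time
  of order 100 s, so shorter windows (few effective samples)
  underestimate the band and make the dwell rule erratic.  Return time
  remains the noisiest indicator — homeostatic turnover keeps the
  trace wandering near the band edge — which is why the dwell window
  exists at all.
* **Steady-state statistics** are reported per lineage (lineage-time
  samples) or per group (group totals normalised by n), with
  population variances.  For uncoupled lineages the normalised group
  total is a mean of n nearly independent lineages, so its variance
  falls roughly as 1/n; for coupled lineages the within-group signals
  are shared, which widens individual-lineage distributions while
  tightening group totals.

## Problem sizes and what the tests show

The validation suite runs metapopulations of Ω = 200 lineages over
horizons of 3000–5000 s, SSA/leap fixture ensembles of 1500
replicates, and 10,000 resampled lineages for removal accounting —
sizes chosen so the whole suite completes in minutes while keeping
Monte-Carlo errors small relative to the effects under test.  Under
the calibrated defaults the ensemble response to removals is close to
linear in the removed fraction, so the decline of the random
protocol's overshoot with group size is small compared to Monte-Carlo
error at these ensemble sizes; the coupling comparison therefore
asserts the inequality within error rather than a resolved decline,
and reads "no trend" for the uneven protocol as any n-dependence below
a quarter of the overshoot magnitude.

The synthetic fixture models (pure death, immigration–death, linear
birth–death) have exact moments and stationary laws and validate the
engine, not the biology.  The HSC runs probe the model's own
behaviour: they show that the implemented transition system with the
calibrated defaults reproduces near-neutral stem-cell turnover,
capacity-bounded S, feedback-held homeostasis and recovery on the
hundreds-to-thousand-second scale.  They do not calibrate to, or
validate against, any experimental haematopoiesis data: parameters are
a canonical set for exploring regulation principles, blood cells are
collapsed to a lymphoid/myeloid dichotomy, there is no spatial
structure, migration, cell-cycle state or explicit injury model.

## Known limitations

* The leap has no criticality handling; very small populations are
  protected only by the `max(ε·x, 1)` floor and the redo rule.
* One slow lineage bounds τ for the whole metapopulation (the
  bottleneck is logged via `RunResult.limiting_counts`).
* The exact SSA refuses coupled groups by design.
* Return-time estimates are sensitive to the band definition and
  recording density; both are configurable and documented above.
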