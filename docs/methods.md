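# Methods

## The lattice agent-based model

Cells occupy single sites of a 2D square lattice representing the surface
of a culture dish. Time advances in discrete update rounds; with the
default `updates_per_day = 2`, a cell dividing at probability 1 every
round approximates a ~12 h minimum cell cycle, and the default clonogenic
phase of 7 days is 14 rounds.

Each round, every live cell is visited once in a freshly randomised order
(asynchronous sequential updating; randomisation removes positional bias
and avoids the conflict resolution a synchronous scheme would need). A
visited cell first dies with probability `death_prob` (default 0), and
otherwise attempts one division with probability

    p(k) = p_init + k * (p_max - p_init) / n_steps,

where `k` is the number of heritable (epi)mutational steps the cell has
accumulated, `p_init` the division probability of the drug-tolerant state
and `p_max` that of the fully resistant state. The interpolation is exact
at both endpoints by construction (the per-cell probability is recomputed
from `k` rather than accumulated, so no floating-point drift).

**Space rule.** A division succeeds if the cell has a reachable empty
site: an empty site among its 8 Moore neighbours (a 4-neighbour
von Neumann variant is available by configuration), or an occupied
neighbour that itself has an empty neighbour — in that case the occupied
cell is pushed into one of its empty neighbour sites and the daughter
takes its place. The daughter's target site and the displaced cell's
destination are both drawn uniformly among admissible options (isotropy).
A cell with no reachable empty site simply does not divide that round
(contact inhibition). Newborns are not processed until the next round; a
displaced cell keeps its place in the current round's order.

**Mutation.** At each successful division, each of the two resulting
daughter cells independently gains one step with probability `mu`, capped
at `n_steps`. With `bidirectional=True` the change is +1 or −1 with equal
odds, floored at 0. With `effect_sd > 0`, the per-step increment is drawn
per event from `Normal(Δ, effect_sd·Δ)` truncated at 0 (Δ the mean
increment), and the cell's probability is clamped to `[p_init, 1]`;
otherwise increments are exactly Δ. Mutation is tied to division —
quiescent cells do not change state.

**Bounds checked on every simulation.** From a single founder the
bounding box side after `t` rounds cannot exceed `1 + 4t` (daughter plus
displacement each extend reach by ≤ 2 sites per round); the population
cannot exceed `2^t` without death. Both are asserted. Colonies are grown
on an automatically sized lattice (`4t + 7` per side) so the boundary is
unreachable; any contact raises an error rather than silently truncating
growth.

The production simulator is a numba-compiled kernel seeded per colony; a
deliberately plain pure-Python re-implementation of the same rules
(`gradres.reference`) exists solely as an independent cross-check, and
the test suite requires the two to produce statistically indistinguishable
final-size distributions.

## Pre-incubation

Cultures adapt for 0–3 weeks in drug before being seeded at clonogenic
density. This bulk phase is modelled *well-mixed*: every cell divides
with its step-dependent probability irrespective of space, daughters
mutate as on the lattice, and the population is randomly down-sampled to
`n_cells` (default 10⁵) whenever it exceeds a ceiling (default 10⁶),
mimicking re-plating. The implementation tracks only the count of cells
per step index, with binomial/multivariate-hypergeometric transitions, so
it is exact and fast. We do not provide a spatial variant of this phase:
a bulk culture that is repeatedly passaged is far better approximated as
well-mixed than as a single static colony, and the spatial constraint is
modelled where it matters — during colony growth. Week 0 returns all
cells at step 0.

A clonogenic cohort (`run_colony_cohort`) draws each colony's founder
step index from the pre-incubation distribution, draws that colony's
`p_max` from a per-colony sampler (reflecting the empirical spread of
resistant growth rates), and grows it on the lattice for the clonogenic
phase.

## Calibration

Division probabilities are not observable; colony sizes are. A
mutation-free cohort at fixed `p` over the clonogenic window gives the
expected final size as a function of `p`; isotonic regression smooths the
Monte-Carlo noise so the map is monotone and invertible by linear
interpolation. `p_init` is the inversion of the *median* tolerant colony
size (tolerant cells are assumed to have little rate variability); each
simulated colony's `p_max` is the inversion of one resistant colony size
resampled with replacement, clamped below at `p_init` with a warning when
the samples overlap. Sizes above the calibrated range clamp to the
largest grid `p` with a warning. Note the map stores mean sizes while the
tolerant calibration uses a median; for the right-skewed size
distributions this gives a mild downward bias in `p_init` (≈0.03 at
p≈0.15 in simulations), well inside the recovery tolerance we test.

A single colony's final size at fixed `p` has an intrinsic coefficient of
variation ≈ 0.28 (early branching noise), which caps how precisely one
size can be inverted: ~88% of single-colony inversions at `p = 0.6` land
within ±0.1 of the truth, independent of map resolution.

## KL model selection

Observed and simulated colony sizes are histogrammed on shared log₂ bins
(powers of two spanning both samples — sizes span orders of magnitude),
with a Laplace pseudocount of 1 per bin before normalisation so every bin
is strictly positive. The score is the Kullback–Leibler divergence in the
direction `D(observed ‖ simulated)`: a parameter pair is penalised for
assigning low probability where data exist. With several pre-incubation
timepoints the grid stores the unweighted mean divergence across
timepoints. The best-fit region collects grid cells with divergence
within a relative tolerance of the minimum; at the cohort sizes we use,
the divergence at the generating cell is pure sampling noise, so "within
twice the minimum" (tolerance 1.0) is the natural region scale used in
the acceptance checks.

## KS mixture test

Under a single-hit model, an intermediate-timepoint colony-size sample
must be a two-component mixture of the tolerant and fully resistant
reference distributions. The mixing weight is fitted by minimising the
KS distance between the observed empirical CDF and
`α F_tol + (1−α) F_res` over an α grid of step 0.01 (both CDFs are step
functions, so the supremum is evaluated exactly at the pooled jump
points). Because α is estimated, significance uses a parametric
bootstrap: `n_boot` samples of the observed size are drawn from the
fitted empirical mixture, α is refitted on each, and the p-value is the
fraction of bootstrap KS distances at least as large as the observed one.
The test statistic is rank-based, so the result is invariant under any
common monotone rescaling of all three samples. Simulations at n = 200
colonies show type-I error compatible with the nominal 5% level and
essentially full power against a unimodal distribution midway between
the two reference modes — the gradual-shift signature.

## Limiting dilution

Wells are scored negative when no colony reaches 50 cells (a colony of
exactly 50 is positive). Under single-hit kinetics,
`ln(fraction negative) = d·ln(1−f)` for seeding dose `d`, so the fit is
ordinary least squares through the origin by default (a free-intercept
option exists; the model warns when the two disagree by more than 10%).
Levels with zero negative wells have an undefined log fraction and are
dropped with a warning (a +0.5 continuity-correction option exists).
The estimate is `cells_per_RIC = 1/(1−e^s)` with delta-method error
`se_s·e^s/(1−e^s)²`.

The slope's standard error defaults to a sandwich form that propagates
the per-level binomial variance of `ln(n/N)`: the log fraction is
strongly heteroscedastic (high doses have both the largest variance and
the most leverage), and the classical residual-based OLS error
understates the sampling spread of the estimate roughly two-fold on
realistic plates, while the binomial form tracks the empirical SD to
within ~10% in simulation. `se_method="residual"` restores the classical
error (exactly 0 on noiseless data).

## Dose–response

Raw luminescence is normalised as
`100·(signal − mean empty)/(mean DMSO − mean empty)` and fitted to
`y = b + (100−b)/(1 + (x/IC₅₀)^k)` on the linear concentration axis by
bounded nonlinear least squares. Initialisation is deterministic:
`b₀ = min(viability)`, `k₀ = 1`, `IC₅₀,₀` the positive concentration
whose viability is closest to `(100+b₀)/2`; bounds `0 ≤ b ≤ 100`,
`0 < k ≤ 10`, `0 < IC₅₀ ≤ 10⁴·max dose`. Fits with IC₅₀ pinned at its
bound or with a collapsed dynamic range (`b → 100`, e.g. flat data) are
flagged `converged=False` rather than silently reported.

## Barcode clone tracing

Frequencies are counts divided by the per-sample total, before any
filtering. The enrichment threshold is the largest entry of the
element-wise mean of the baseline frequency vectors; a barcode is called
positively selected in a sample when its frequency *strictly* exceeds
that threshold. Shannon diversity is reported in nats. Spearman
correlations between samples are computed on the union of enriched
barcodes; hierarchical clustering of that union uses complete linkage on
Euclidean distances of log₁₀ frequencies with a half-read
pseudofrequency guarding zeros.

## What the synthetic generators emulate — and what they do not

* Colony sizes: lognormal (or lognormal-mixture) cell counts, rounded
  half-up and floored at 1. The empirical distribution family of real
  colony sizes is unknown; lognormal is a modelling choice that matches
  right-skewed, order-of-magnitude-spanning sizes, nothing more.
* Limiting dilution: exact single-hit kinetics
  (`negatives ~ Binomial(wells, (1−f)^d)`). Real plates can deviate from
  single-hit behaviour (cooperation, drug gradients); passing recovery
  tests validates the estimator, not the kinetics assumption.
* Barcodes: a fixed clone set per condition is expanded in every
  replicate (heritable pre-existing advantage) with per-replicate growth
  factors and multinomial sequencing noise. Defaults: 1000 barcodes,
  lognormal(0, 0.5) baseline abundance, 1% expanded per condition,
  lognormal(3, 0.5) growth factors (~20× median expansion over the
  4-week selection), depth 10⁶ reads, 2 baseline samples, 3 conditions ×
  4 replicates mirroring quadruplicate cultures. No sequencing-error or
  library-bottleneck model: counts in, statistics out.
* Viability plates: the four-parameter curve with plate background and
  multiplicative Normal noise; no edge effects or drift.

Consequently, green tests demonstrate that each estimator recovers the
truth *under its own generative assumptions* at realistic sizes — they
cannot certify those assumptions for any particular real experiment.

## Problem sizes in the test-suite and acceptance script

The full-scale analysis this package is built for uses very large
simulated cohorts (10⁵ colonies per grid cell); the shipped checks use
cohorts of 2000 colonies per cell on a 4 μ × 6 n grid with a single
3-week timepoint, a choice that keeps the whole validation under ~10
minutes on one CPU while leaving the rank structure of the KL surface
unambiguous (the single-step model is worse by ~3 orders of magnitude).
Study conditions for the recovery checks: `p_init = 0.1`, per-colony
`p_max ~ Uniform(0.7, 0.9)`, truth at `μ = 0.05`, `n = 30`; mixture-test
references are lognormal(1.5, 0.5) and lognormal(6, 0.5) samples of 300
colonies (tolerant ≈ 5-cell colonies, resistant ≈ 500-cell colonies,
matching the tolerant/resistant size split), observed samples of 200;
limiting-dilution plates use the standard design (top density 400
cells/well plus five 2-fold dilutions, 10 wells per level) at a true
frequency of 1 RIC per 500 cells, inside the experimentally reported
1:338–1:660 range. The acceptance script reports percentages on the 0–100
scale and uses 10 repeats for the KL grid study, 200/100 repeats for the
mixture-test calibration/power, and 200 simulated experiments for the
limiting-dilution and dose–response recoveries.

## Known limitations

* The lattice neighbourhood, update synchrony and divisions-per-day of
  the modelled experimental system are not uniquely determined by the
  available descriptions; the defaults above (Moore, asynchronous
  sequential, 2/day) are explicit choices, and the neighbourhood is
  configurable.
* "Mutation probability" is interpreted per daughter per division (so a
  division can advance both offspring independently).
* The KL direction, binning and pseudocount are implementation decisions
  recorded here and in output metadata; results are reproducible
  bit-for-bit given seed and configuration.
* No likelihood or posterior over the ABM parameters: model selection is
  the KL ranking on a user-chosen grid. No nutrient fields, migration,
  3D growth, or pharmacokinetics.
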