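# gradres

**Does acquired drug resistance arise in a single (epi)mutational hit, or by
gradual multi-step adaptation?**

When cancer cells that initially only *tolerate* a targeted drug (e.g. an
ALK tyrosine-kinase inhibitor in *EML4-ALK* lung cancer cells) eventually
produce robustly growing resistant colonies, two generative stories are
compatible with the endpoint: a rare single heritable change that flips a
tolerant cell to full resistance, or many small heritable increments that
ratchet fitness upward. The two stories leave different fingerprints in
*colony-size distributions*: a single hit predicts a bimodal mix of small
tolerant and large resistant colonies, while gradual adaptation predicts a
homogeneous, progressively shifting distribution.

`gradres` implements the quantitative machinery to tell these apart, for
computational biologists analysing clonogenic, limiting-dilution, viability
and clone-tracing experiments:

* **Lattice agent-based model** — cells on a 2D lattice (the culture-dish
  surface) divide with probability `p(k) = p_init + k (p_max − p_init)/n`,
  where `k` counts accumulated (epi)mutational steps out of `n`; each
  daughter gains a step with probability `μ` per division. Division needs
  reachable space: an empty neighbour site, or an empty site behind a single
  intervening cell, which is pushed outward. Optional cell death,
  bidirectional steps and variable step effects.
* **KL model selection** — simulated colony cohorts across a `(μ, n)` grid
  are scored against observed colony sizes by
  `D(P‖Q) = Σᵢ Pᵢ ln(Pᵢ/Qᵢ)` on shared log₂ size bins; the best-fit region
  identifies the number of steps the data support.
* **KS mixture test** — the single-hit null says observed sizes are a
  mixture `α F_tol + (1−α) F_res` of the tolerant and resistant reference
  distributions; `α` is fitted by minimising the Kolmogorov–Smirnov
  distance, with a parametric bootstrap p-value.
* **Limiting dilution** — from negative-well counts, `ln(fraction negative)`
  is regressed through the origin on cells seeded per well; the frequency of
  resistance-initiating cells (RICs) follows as
  `cells_per_RIC = 1/(1 − e^slope)` with delta-method error
  `se_slope · e^slope/(1 − e^slope)²`.
* **Dose–response** — viability normalised to empty/DMSO wells is fitted to
  `y = b + (100 − b)/(1 + (x/IC₅₀)^k)`.
* **Barcode clone tracing** — enrichment calls against the maximal averaged
  baseline barcode frequency, Shannon diversity `H = −Σ f ln f`, and
  replicate/condition Spearman correlation + hierarchical clustering to test
  for pre-existing tolerant clones.
* **Synthetic data** — seeded generators for every input, so the entire
  pipeline runs and is tested without any external dataset.

## Worked example

Simulate a cohort of 1000 colonies whose founders spent 3 weeks adapting
(n = 30 steps, μ = 0.05), then ask the KL scan which step counts explain it:

```python
import numpy as np
from gradres import SimulationParams, run_colony_cohort, GradualityScan

truth = SimulationParams(p_init=0.1, p_max=0.8, n_steps=30, mu=0.05)
sampler = lambda r: r.uniform(0.7, 0.9)        # per-colony maximal rate
target = run_colony_cohort(truth, preincubation_weeks=3, n_colonies=1000,
                           p_max_sampler=sampler, rng=np.random.default_rng(0))
scan = GradualityScan({3: target}, p_init=0.1, p_max_sampler=sampler)
res = scan.fit(mu_values=[0.01, 0.05, 0.1], n_values=[1, 10, 30, 100],
               reps=1000, seed=1)
print(res.summary())
```

```
KL model selection over (mu, n_steps)
=====================================
grid            : 3 mu x 4 n (1000 colonies per cell)
minimum KL      : 0.0013 nats at mu=0.05, n=30
KL at n=1 (min over mu) : 5.4255 nats
```

The generating cell (μ = 0.05, n = 30) minimises the divergence, while the
single-hit model (n = 1) is four orders of magnitude worse at every mutation
probability — the data are unmistakably gradual.

A limiting-dilution plate simulated at 1 RIC per 500 cells, scored and
fitted:

```python
from gradres import generate_limiting_dilution_plates, LimitingDilutionModel

plate = generate_limiting_dilution_plates(1/500, top_densities=[400], seed=7)
print(LimitingDilutionModel(plate).fit().summary())
```

```
Limiting-dilution single-hit fit
================================
dilution levels used : 6
intercept            : zero
slope (per cell)     : -0.00212336 +/- 0.00067
per-cell frequency   : 0.00212111
cells per RIC        : 471.5 +/- 149
```

The true value, 500 cells per RIC, sits well inside one reported standard
error.

A command-line interface mirrors the library
(`gradres synth | simulate-colonies | calibrate | sweep-grid | mixture-test |
ld-fit | dr-fit | barcode-analyze | run-pipeline`); every invocation writes a
JSON manifest recording parameters, seed and input digests.

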