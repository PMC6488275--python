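# Methods

## Population model

Time advances in fixed 1-minute steps.  Every growing cell elongates
multiplicatively, `size ← size · (1 + g)^dt` with fractional growth rate
`g` per minute (default 0.006, i.e. size doubling in ≈116 min; the
alternative published value 0.0029 is selectable in the configuration).
Cells are agents with a private state: current size, birth size and time,
age, cyclin amount, phase (growing or septated), and a rule-specific
threshold drawn once at birth.

A division rule decides each minute whether a growing cell triggers
division:

| rule  | trigger | per-cell threshold |
|-------|---------|--------------------|
| sizer | size ≥ θ | θ ~ N(14.5, 1.2) |
| adder | size − birth size ≥ θ | θ ~ N(6.75, 1) |
| timer | age ≥ θ | θ ~ N(100, 5) min |
| pdiv  | u < Hill(size), u ~ Uniform(0,1) | — |
| cdc13 | cyclin statistic ≥ θ | θ ~ N(θ̄, σ_θ) |

A configurable `min_cycle_duration` suppresses all triggers below a minimal
age (default 0).  Gaussian thresholds are truncated at 0 by redrawing.

On division (optionally after a non-elongating septated period of τ
minutes; the trigger size is then the recorded division size) the mother is
replaced by two daughters of sizes `1.05·D/2 ± ε`, `ε ~ N(0, 1)`; ε is
redrawn if a daughter would be non-positive, which stays unbiased because ε
is symmetric, with a capped retry count for degenerate mothers far below
the noise scale.  Each completed cycle emits a record
(birth/division sizes and times); the founder cells' first divisions have
no observed birth and are excluded unless explicitly requested.
`division_time` is the trigger (septation-entry) time, so durations and
Fantes quantities do not depend on τ.

The engine stores the population as one numpy array per attribute
(struct-of-arrays), which keeps a 1000-minute run with ~10⁴ final cells at
a fraction of a second; single-cell operations (`grow_step`,
`division_decision`, `cdc13_update`, `divide`) expose the same arithmetic
on individual `CellState` objects and are cross-checked against the engine
in the tests.

### Cyclin (Cdc13) accumulation rule

Per minute a growing cell gains `synthesis_rate` cyclin units (times
current size in `size_proportional` mode, in which the Gaussian synthesis
noise sd scales with size as well — noise generated by the synthesis
machinery scales with the machinery), plus an optional size-independent
`basal_synthesis_rate`, minus `degradation_rate`, floored at 0.  Division
triggers when the statistic selected by `threshold_mode` (amount, or
concentration = amount/size) reaches the per-cell threshold.  Daughters
start at `0.7 · birth size` cyclin units (anaphase degradation followed by
rapid re-accumulation is not resolved below the 1-minute step).

The four mode combinations behave very differently and none of the
published constants (synthesis 0.07/min, threshold 6 ± 0.3, birth level
0.7·size) is consistent under every reading:

* **size-proportional + concentration** (simulator default): concentration
  follows dC/dt = 0.07 − g·C independently of size, giving realistic
  ≈110-minute cycles — but the rule is then a timer in disguise: birth
  sizes random-walk and there is no size-homeostatic steady state.
* **absolute + concentration**: the threshold is unreachable at realistic
  sizes.
* **amount thresholds with the printed constant 6**: cycles of ~16 min and
  no positive steady state (sizes collapse).

## Synthetic cytometry generator

The generator's task is to produce per-cell tables with the statistical
structure the analyses assume.  For the shift-up (division-blocked)
experiment it therefore uses the only homeostatic reading of the
accumulation model: size-proportional synthesis with an **amount**
threshold, rescaled to θ̄ = 79 AU (σ_θ = 4, preserving the published 5%
relative threshold noise).  Under this reading the accumulated amount reads
out current size, `A ≈ 11.74·s − 10.97·b` for birth size `b`, the
steady-state birth size is ≈7 length units (division at ≈13.3), and the
division-size CoV is ≈9%.  Fluorescence units are arbitrary throughout; no
correspondence to published AU values is implied.

`synth_snapshot` runs the P(Div) rule with a 30-minute septation period for
5 mean cycle times of burn-in plus a 100-minute window and samples rows
from the pooled late snapshots.  `synth_cyclin_pair` runs the cyclin rule
to burn-in, samples one snapshot as the dividing (permissive) condition,
then disables new division triggers — cells already septated still complete
their split — for `restrictive_extra_minutes` (default 35, just above the
septation period, emulating a short shift-up) and samples the blocked
(restrictive) condition.  Measured fluorescence is the thresholded cyclin
statistic times unit-mean lognormal measurement noise with CV
`expression_noise_cv` (default 0.05, a typical measurement CV for bright
fluorophores; chosen at design time because the brightest-10 threshold
estimator's extreme-value bias grows with the within-bin spread — see
"Estimator bias" below).

What the generator does *not* emulate: optics and autofluorescence,
segmentation error, cell-cycle–dependent probe maturation, the linear-
plus-plateau growth phases of real fission yeast, or G1/S size control.
Passing tests therefore demonstrate correctness of the estimators on data
satisfying the model's assumptions, not performance on real images.

## P(Div) estimation

`bin_fraction_septated` bins cells into uniform size bins spanning
[floor(min size), ceil(max size)] (default width 1), drops bins with fewer
than `min_count = 10` cells, and returns per-bin septated fractions.
`fit_hill` runs unweighted nonlinear least squares (scipy `curve_fit`) of
fraction against bin centre, initialised at pmax₀ = max fraction, EC50₀ =
centre nearest half-max, n₀ = 4, with bounds pmax ∈ (0,1], EC50 ∈ (0, max
size], n ∈ (0,100]; count-weighted fitting is available but off by
default.  Non-convergence, or a fit pinned at a bound, is reported through
`converged=False` rather than an exception, and a per-time-point series
isolates failures entry by entry.

`rate_from_fraction` offers the literal published normalisation
(fraction/τ) and the steady-state renewal inversion `h = f/(τ(1−f))`, the
exact inverse of the occupancy relation `f = hτ/(1+hτ)`.  Both are provided
because the literal form cannot exceed 1/τ, while the renewal inversion
maps a high plateau fraction to the much larger per-minute hazards the
model actually uses.

## Homeostasis metrics

The Fantes fit is ordinary least squares of extension (division −
birth size) on birth size over completed cycles only; founder-generation
divisions are excluded because their "births" are the division-sized
initial population.  CoV uses the sample (n−1) standard deviation.
Box summaries use linear-interpolation quartiles; each whisker extends by
the distance to the furthest point or 1.5×IQR, whichever is smaller.

`sweep_grid` re-runs the P(Div) simulation over an EC50 × n grid (defaults
8..20 × 2..30 step 2, 3 replicates) with per-cell seeds derived from
`SeedSequence([seed, i, j, r])`, so cells are independent but
reproducible; failures are recorded as NaN without aborting the sweep.

## Cyclin-threshold pipeline

Cells are binned into 8 equal-width bins spanning the observed division
sizes (septated permissive cells; min to max).  The per-bin threshold is
the mean of the 10 brightest permissive cells (bins with fewer than 10
cells are excluded); the global threshold is the unweighted mean of the
per-bin thresholds.  P(Septation) is the septated fraction per bin
(missing, not 0, for empty bins); P(suprathreshold) the strict fraction of
restrictive cells above the threshold; P(overlap) the fraction of
permissive cells inside the overlap interval, by default derived per bin as
[25th percentile of restrictive fluorescence, 95th percentile of permissive
fluorescence] — the region where the dividing population still looks like
the bulk of the non-dividing one.  The 25th-percentile floor was chosen
over a 5th-percentile one because the restrictive distribution has a long
lower tail (birth-size memory) that makes an extreme-quantile bound jump
between bins.  Quantiles use linear interpolation throughout, and all
intervals used are reported with the results.

### Estimator bias

The mean-of-brightest-10 threshold is an extreme-value statistic: with
~300 cells per bin it averages the top ≈3%, which for a near-Gaussian
within-bin distribution sits ≈2 SD above the true threshold.  With 5%
threshold noise and 5% measurement CV this yields a ≈10–15% upward bias —
visible in the recovery tests, which accordingly assert recovery within
15% and not better.  The same bias shifts the suprathreshold curve toward
larger sizes and is the main reason the septation/suprathreshold
correlation sits near 0.9 rather than its unbiased renewal-oracle value of
≈0.97.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; CLI stages derive per-stage seeds as
  `SeedSequence([seed, crc32(stage)])`.  Identical config + seed gives
  bit-identical outputs.
* The Hill curve is evaluated in the overflow-safe form
  `pmax/(1+(EC50/s)^n)`; `pmax = 0` is admitted as the degenerate
  never-dividing limit so that no-division control configurations are
  expressible.
* Size-bin assignment is half-open [lo, hi) with the last bin closed;
  interior edge values belong to the right bin.
* CSV interchange writes 12 significant digits; schema violations name the
  offending column and line.
* Known limitations: no spatial or geometric cell model; no lineage-tree
  statistics; the cyclin rule does not resolve mitotic degradation kinetics
  within a step; the P(Div) comparison draw is Uniform(0,1) — the model has
  no size-independent baseline division pathway, so the asymptotic Fantes
  slope of the pure hazard model is −1 and measured slopes near −0.98
  reflect finite-window censoring of the last incomplete generation.
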