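# Methods

## The design-analysis model

The package evaluates a two-independent-group comparison analysed with a
two-tailed pooled-variance (Student) *t*-test on the standardized scale.
The generative model is deliberately the simplest one compatible with that
test: group 1 ~ N(d, 1), group 2 ~ N(0, 1), equal variances, so the
population mean difference *is* Cohen's *d*. The estimate
d̂ = (x̄₁ − x̄₂)/s_pooled re-estimates the pooled SD from each simulated
sample.

Given a plausible effect specification, `n_sims` replicate experiments are
generated and reduced to three quantities:

* power — the fraction of replicates with p < α;
* Type M (exaggeration ratio) — mean |d̂| among significant replicates,
  divided by the plausible |d|;
* Type S (sign error) — the fraction of significant replicates whose d̂
  opposes the sign of the plausible effect.

Type M and Type S condition on significance. When no replicate is
significant they are reported as explicit `None` sentinels with
`n_significant = 0` — never coerced to 0 or NaN — because designs with
essentially zero power are precisely the warning case.

Why these three numbers move together: only estimates with
|d̂| ≥ d_crit = t₁₋α/₂,ν √(1/n₁ + 1/n₂) can reject the null. When d_crit is
far above the plausible d (small n), conditioning on significance truncates
the sampling distribution of d̂ from below, inflating its conditional mean
(Type M) and leaving non-trivial mass on the wrong side of zero (Type S).
Note this is purely a selection effect, not a bias of d̂ itself.

## Plausible effects

* Point mode: a single d. d = 0 is accepted (for α-calibration checks) but
  Type M / Type S are undefined there and raise/flag accordingly.
* Interval mode: d varies over [lower, upper], either uniformly or as a
  doubly truncated normal with mean at the interval center and standard
  deviation `sd_fraction × (upper − lower)`. The default `sd_fraction` of
  1/6 gives a normal-like shape with appreciable mass near the bounds
  (greater uncertainty); 1/10 yields a distribution whose truncation
  removes < 0.3% of the normal's mass, i.e. essentially an untruncated
  normal.

Interval draws use the inverse-CDF transform (a uniform deviate mapped
through the truncated quantile function): exact support, fixed cost per
draw, and trivially reproducible.

In interval mode each replicate's data are generated under a freshly drawn
true effect (hierarchical scheme); `DesignConfig(fixed_center=True)`
collapses the distribution to its center for comparison. The Type M
denominator and Type S sign reference in interval mode are the interval
center — the most plausible single effect — so the exaggeration ratio reads
as overestimation *of the most plausible effect*, not of each replicate's
own draw.

## Simulation engine

* `n_sims` defaults to 100,000; at that size the Monte-Carlo SE of a power
  estimate is ≤ 0.16 percentage points. The CLI warns when a smaller value
  is requested.
* Replicates are generated in fixed blocks of 4,096, each block with its own
  `SeedSequence(seed, spawn_key=(block,))` substream, and every block is
  generated at full size then sliced. Consequences: memory stays bounded
  regardless of n_sims; results depend only on (spec, n₁, n₂, seed); and a
  shorter run is bit-for-bit a prefix of a longer run with the same seed.
* `max_total_draws` (default 2×10⁹ normal deviates) guards a single call;
  larger ensembles should be split across seeds and pooled.
* Two strategies: `data_sim` (default) simulates raw samples;
  `ncp_sim` draws t from the noncentral t and back-transforms via
  d̂ = t·√(1/n₁+1/n₂). Because d̂ and t share the same pooled SD, that
  relation is an identity, so the two strategies sample the *same*
  distribution; `ncp_sim` is simply faster and `data_sim` remains the
  reference implementation of the described procedure.

## Analytic oracle

For point effects the pooled t is noncentral-t distributed with
ν = n₁+n₂−2 and ncp = d √(n₁n₂/(n₁+n₂)); power and Type S are tail
probabilities, and Type M is E[|T| | |T| > t_crit]·√(1/n₁+1/n₂)/|d|. By the
identity above these closed forms are exact for the simulated estimates, so
oracle-vs-simulation checks need only Monte-Carlo tolerances (3 SE) with no
systematic offset. The oracle is a verification and search device; reported
results come from simulation, which also covers interval mode.

Numerical choices:

* The Type M expectation is integrated over the chi-squared mixture
  representation T = X/√(U/ν), X ~ N(ncp, 1), U ~ χ²_ν: the inner normal
  partial expectations are closed-form and the outer one-dimensional
  integral (adaptive quadrature, relative tolerance 1e−8, integrated over
  the 1e−13…1−1e−13 quantile range of χ²_ν) is stable at any ν. The
  noncentral-t *density* itself overflows for ν in the several hundreds,
  which rules out naive quadrature. Non-convergence raises with the error
  estimate rather than returning a doubtful value.
* Extreme far-tail CDF values of the noncentral t can return NaN at large
  ν; the oracle falls back to the large-ν normal limit N(ncp, 1) for the
  offending tail, where that tail is numerically negligible anyway.

## Planning workflows

* Prospective: the smallest balanced per-group n with *analytic* power
  ≥ target − 0.002 (bracket + bisection), with simulated metrics then
  reported at that n. The 0.002 slack reflects that a simulation-based
  search scatters a step or two around the exact crossing of a locally very
  flat power curve; the deterministic rule reproduces conventional printed
  sample sizes at that granularity and is itself exactly reproducible. The
  search errors above a configurable cap (default 10⁶/group) with the
  advice that the effect is too small to plan for.
* Retrospective: simulation + reduction at fixed (n₁, n₂); unbalanced
  groups are accepted (an odd total such as 67 is evaluated as its actual
  33/34 split).
* Sensitivity grids: one prospective row per (d, target power) pair;
  `power_curve` evaluates one effect across an n-grid, returning plot-ready
  tables (the package renders no figures).
* Prospective planning with an interval spec plans at the interval center
  and then reports distribution-mode metrics at the chosen n — an extension
  beyond the point-valued planning workflow, flagged in the docstring.

## What the generator does and does not emulate

The simulator draws exactly the model the *t*-test assumes: normal
outcomes, equal variances, independent observations. Passing tests
therefore show that the metrics are computed correctly *under the model*,
not that real studies satisfy it: skewed or heavy-tailed outcomes, unequal
variances (where Welch's test would be appropriate), clustering, covariate
adjustment and measurement unreliability are all outside scope, and real
Type M/S risks can only be worse under such violations. One-tailed tests,
paired designs and other effect-size measures are likewise not supported.

## Testing and problem sizes

Unit and property tests run at a reduced profile of 20,000 replicates
(Monte-Carlo tolerances widen automatically as 4·SE), which keeps the full
suite within a few minutes on one CPU; end-to-end checks of the headline
scenarios use the reference 100,000 replicates, where the largest run
(252 per group) draws ~5×10⁷ normal deviates in about a second. Hypothesis
property tests are derandomized. The acceptance script
(`scripts/acceptance.py --seed S --out F`) recomputes every headline number
at 100,000 replicates from a single user-supplied seed.

## Known limitations

* Type M's Monte-Carlo SE is reported from the conditional sample; for
  designs with power near α the significant subsample is small and the SE
  correspondingly unstable.
* The normal-approximation CI for Cohen's d (se = √((n₁+n₂)/(n₁n₂) +
  d²/(2(n₁+n₂)))) is a large-sample form; no Hedges small-sample
  correction is applied anywhere, consistently on both the observed-study
  and simulation sides.
* The analytic oracle covers point effects only; interval-mode results
  rest on simulation alone.
* Printed reports round to two decimals; full precision is always
  available on the result objects.
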