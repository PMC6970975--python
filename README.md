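# designanalysis

Design analysis for two-independent-group comparisons on Cohen's *d*:
Monte-Carlo estimation of **power**, **Type M error** (exaggeration ratio)
and **Type S error** (sign error), run *prospectively* (how large must my
study be?) or *retrospectively* (what inferential risks does this completed
or planned design carry?).

It is aimed at researchers — in psychology, clinical research and any field
that compares two groups with a *t*-test — who want more than a power
number. An underpowered study does not merely risk missing an effect: among
the results that *do* reach significance, estimates are systematically
inflated (the winner's curse) and can even carry the wrong sign. Design
analysis quantifies all three risks under a *plausible* effect size chosen
from theory or meta-analysis, never from a single noisy estimate.

## The model

Two groups of sizes n₁, n₂ are compared with a two-tailed pooled-variance
(Student) *t*-test at level α. Outcomes are unit-variance normal, group 1
shifted by the true standardized effect *d*, so the estimate is Cohen's
d̂ = (x̄₁ − x̄₂)/s_pooled. Given a plausible effect *d* (or a distribution of
plausible effects), the experiment is replicated `n_sims` = 100,000 times
and:

- **power** = (# significant replicates) / n_sims,
- **Type M** = mean(|d̂| over significant replicates) / |d|,
- **Type S** = (# significant replicates with sign(d̂) ≠ sign(d)) / (# significant).

Only estimates with |d̂| ≥ d_crit = t₁₋α/₂,ν · √(1/n₁ + 1/n₂) can be
significant (ν = n₁ + n₂ − 2); when d_crit ≫ d, significance *forces*
exaggeration. A closed-form oracle based on the noncentral *t* distribution
(ncp = d·√(n₁n₂/(n₁+n₂))) cross-validates the simulation and drives the
sample-size search.

Uncertainty about the plausible effect can be expressed as a uniform or a
doubly truncated normal distribution on an interval [lower, upper]; each
replicate then draws its own true effect before generating data.

## Worked example

A trial compared an innovative cognitive treatment (n = 31, M = 114,
SD = 16) with a traditional one (n = 31, M = 100, SD = 15):

```
$ designanalysis effectsize --n1 31 --m1 114 --sd1 16 --n2 31 --m2 100 --sd2 15
Cohen's d = 0.90 (95% CI 0.38-1.43)
t(60) = 3.554, p = 0.0007464 (significant at alpha = 0.05)
critical |d| at this design: 0.51
```

Significant, with an apparently large effect — but the CI is wide, and the
researchers' own a-priori plausible effect was d = 0.25. A retrospective
design analysis at that plausible effect:

```
$ designanalysis --seed 1 retrospective --n1 31 --n2 31 --effect-d 0.25
Design analysis (point effect d = 0.25; n1 = 31, n2 = 31, alpha = 0.05, 100000 simulations, seed 1)
 power typeS typeM
  0.16  0.01  2.59
```

Power is only 16%; a significant result is expected to overstate the
plausible effect 2.6-fold, with a 1% chance of the wrong sign. The observed
d = 0.90 is exactly what a true d = 0.25 looks like after selection on
significance. Planning a new study properly:

```
$ designanalysis --seed 1 prospective --effect-d 0.25 --power 0.80
Prospective design analysis (point effect d = 0.25, target power 0.8, alpha = 0.05)
     d  power      n typeS typeM
  0.25   0.80    251  0.00  1.13
```

About 251 participants per group are needed for 80% power, and even then a
significant estimate still overshoots by ~13% on average. The same analysis
with the plausible effect expressed as a doubly truncated normal on
[0.20, 0.60] (sd = interval/6):

```
$ designanalysis --nsims 100000 --seed 1 retrospective --n1 31 --n2 31 \
      --effect-limits 0.20,0.60 --effect-dist normal
 power typeS typeM
  0.35  0.00  1.73
```

In Python the same workflow is:

```python
from designanalysis import DesignConfig, make_point_effect, retrospective_design

res = retrospective_design(31, 31, make_point_effect(0.25),
                           DesignConfig(n_sims=100_000, seed=1))
print(res.power, res.type_s, res.type_m)   # 0.162  0.010  2.591
```

See also `designanalysis sensitivity` (planning tables over effect × power
grids), `designanalysis curve` (power/Type M/Type S versus n, plot-ready)
and `designanalysis fixtures list` (built-in worked scenarios).

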