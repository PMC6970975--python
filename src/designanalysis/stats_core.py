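"""Deterministic two-group statistics on the standardized (Cohen's *d*) scale.

Everything downstream — the Monte-Carlo engine, the analytic oracle and the
planning workflows — reduces to the three quantities defined here:

* the pooled-variance (Student) two-sample *t*-test,
* Cohen's *d* with a normal-approximation confidence interval, and
* the *critical d*: the smallest absolute standardized effect estimate that
  reaches two-tailed significance at a given alpha and sample size.

The test variant is deliberately the equal-variance Student test (not Welch):
the simulation model generates both groups with unit variance, and the
critical-*d* algebra below assumes the pooled statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "EffectEstimate",
    "cohens_d",
    "pooled_t_test",
    "critical_d",
    "t_and_d_from_moments",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: size, mean and standard deviation.

    ``mean`` and ``sd`` are in the units of the outcome variable; ``sd``
    is the sample standard deviation (ddof=1).
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ValueError(f"n must be an integer >= 2, got {self.n!r}")
        if not np.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean!r}")
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"sd must be a positive real, got {self.sd!r}")


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample *t*-test outcome at a configured alpha."""

    t_statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class EffectEstimate:
    """Cohen's *d* with its standard error and confidence interval."""

    d: float
    se_d: float
    ci_lower: float
    ci_upper: float
    ci_level: float


def _validate_alpha(alpha: float, name: str = "alpha") -> None:
    if not (np.isfinite(alpha) and 0.0 < alpha < 1.0):
        raise ValueError(f"{name} must lie in (0, 1), got {alpha!r}")


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    df = g1.n + g2.n - 2
    return float(
        np.sqrt(((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df)
    )


def cohens_d(g1: GroupSummary, g2: GroupSummary, ci_level: float = 0.95) -> EffectEstimate:
    """Cohen's *d* between two summarized groups, with a confidence interval.

    ``d = (mean1 - mean2) / s_pooled`` where the pooled standard deviation
    weights each group's variance by its degrees of freedom. The sign is
    positive when group 1's mean exceeds group 2's.

    The interval uses the large-sample normal approximation with

        se_d = sqrt((n1 + n2)/(n1 * n2) + d^2 / (2 (n1 + n2)))

    and ``d ± z * se_d``. No small-sample (Hedges) correction is applied.
    """
    _validate_alpha(ci_level, "ci_level")
    d = (g1.mean - g2.mean) / _pooled_sd(g1, g2)
    n1, n2 = g1.n, g2.n
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    return EffectEstimate(
        d=float(d),
        se_d=float(se),
        ci_lower=float(d - z * se),
        ci_upper=float(d + z * se),
        ci_level=float(ci_level),
    )


def pooled_t_test(g1: GroupSummary, g2: GroupSummary, alpha: float = 0.05) -> TTestResult:
    """Two-tailed Student (equal-variance pooled) *t*-test from group summaries.

    df = n1 + n2 - 2. The ``significant`` flag is ``p < alpha``.
    """
    _validate_alpha(alpha)
    df = g1.n + g2.n - 2
    sp = _pooled_sd(g1, g2)
    t = (g1.mean - g2.mean) / (sp * np.sqrt(1 / g1.n + 1 / g2.n))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(
        t_statistic=float(t),
        df=int(df),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=float(alpha),
    )


def critical_d(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Smallest |d| estimate attaining two-tailed significance.

    Only estimates with ``|d_obs| >= critical_d`` can reject the null; in an
    underpowered design this threshold sits far above the plausible effect,
    which is the mechanism behind the winner's curse (every significant
    estimate is necessarily inflated).

        critical_d = t_{1-alpha/2, n1+n2-2} * sqrt(1/n1 + 1/n2)
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n1, n2 >= 2, got n1={n1}, n2={n2}")
    _validate_alpha(alpha)
    df = n1 + n2 - 2
    return float(stats.t.ppf(1 - alpha / 2, df) * np.sqrt(1 / n1 + 1 / n2))


def t_and_d_from_moments(
    n1: int,
    mean1: np.ndarray,
    var1: np.ndarray,
    n2: int,
    mean2: np.ndarray,
    var2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled t, two-tailed p and Cohen's d from sample moments.

    ``var1``/``var2`` are sample variances (ddof=1). Accepts arrays of
    per-replicate moments; this is the hot path of the simulation engine, kept
    here so the engine and the observed-study API share one formula.
    """
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * var1 + (n2 - 1) * var2) / df)
    diff = mean1 - mean2
    d = diff / sp
    t = diff / (sp * np.sqrt(1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, d
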