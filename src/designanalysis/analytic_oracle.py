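"""Closed-form counterparts of power, Type M and Type S for point effects.

Under the equal-variance model the pooled *t* statistic follows a noncentral
*t* distribution with ``df = n1 + n2 - 2`` and noncentrality
``ncp = d * sqrt(n1 n2 / (n1 + n2))``. Power and Type S are direct tail
probabilities of that distribution; Type M is the truncated expectation
``E[|T| | |T| > t_crit] * sqrt(1/n1 + 1/n2) / |d|``, computed by quadrature.

Because the sample Cohen's *d* and the pooled *t* share the same pooled SD,
``d_obs = t * sqrt(1/n1 + 1/n2)`` holds identically, so for point effects
these closed forms describe the simulated estimates exactly (up to
quadrature error): simulation and oracle differ only by Monte-Carlo noise.
The oracle cross-validates the engine and seeds the sample-size search;
reported results come from simulation, which also covers the interval-mode
effect distributions the closed forms do not.

The Type M integral is evaluated over the scale-mixture representation
``T = X / sqrt(U/df)`` with ``X ~ N(ncp, 1)`` and ``U ~ chi2(df)``: the inner
normal partial expectations are closed-form, leaving a one-dimensional
integral in ``U`` that stays numerically stable at any df (the noncentral-t
density itself overflows for df in the several hundreds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "NoncentralParams",
    "noncentral_params",
    "analytic_power",
    "analytic_type_s",
    "analytic_type_m",
]

_QUAD_RTOL = 1e-8


@dataclass(frozen=True)
class NoncentralParams:
    df: int
    ncp: float
    t_crit: float


def noncentral_params(d: float, n1: int, n2: int, alpha: float) -> NoncentralParams:
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n1, n2 >= 2, got n1={n1}, n2={n2}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    df = n1 + n2 - 2
    return NoncentralParams(
        df=df,
        ncp=float(d * np.sqrt(n1 * n2 / (n1 + n2))),
        t_crit=float(stats.t.ppf(1 - alpha / 2, df)),
    )


def _tail_probs(df: int, ncp: float, t_crit: float) -> tuple[float, float]:
    """(upper, lower) rejection-tail probabilities of nct(df, ncp).

    scipy's noncentral-t tails can return nan in the extreme far tail at
    large df; fall back to the large-df normal limit T ~ N(ncp, 1) there,
    where the offending tail is astronomically small anyway.
    """
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(upper):
        upper = float(stats.norm.sf(t_crit - ncp))
    if not np.isfinite(lower):
        lower = float(stats.norm.cdf(-t_crit - ncp))
    return float(upper), float(lower)


def analytic_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """P(|T| > t_crit) under the design's noncentral t; equals alpha at d = 0."""
    p = noncentral_params(d, n1, n2, alpha)
    upper, lower = _tail_probs(p.df, p.ncp, p.t_crit)
    return upper + lower


def analytic_type_s(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """P(sign error | significant): the wrong-sign tail over both tails."""
    if d == 0:
        raise ValueError("Type S is undefined at d = 0")
    p = noncentral_params(abs(d), n1, n2, alpha)
    upper, wrong = _tail_probs(p.df, p.ncp, p.t_crit)
    return wrong / (wrong + upper)


def _e_abs_t_significant(df: int, ncp: float, t_crit: float) -> float:
    """E[|T| ; |T| > t_crit] for T ~ nct(df, ncp), via the chi2 mixture.

    Conditional on U = u, T = X / w with w = sqrt(u/df) and X ~ N(ncp, 1), so

        E[|T|; T >  t_crit | u] = (1/w) E[ X; X >  t_crit w]
        E[|T|; T < -t_crit | u] = (1/w) E[-X; X < -t_crit w]

    with E[X; X > a] = ncp Phi(ncp - a) + phi(a - ncp) and
    E[-X; X < -a] = -ncp Phi(-a - ncp) + phi(a + ncp).
    """

    def integrand(u: float) -> float:
        w = np.sqrt(u / df)
        a = t_crit * w
        upper = ncp * stats.norm.cdf(ncp - a) + stats.norm.pdf(a - ncp)
        lower = -ncp * stats.norm.cdf(-a - ncp) + stats.norm.pdf(a + ncp)
        return stats.chi2.pdf(u, df) * (upper + lower) / w

    # Integrate over the effective support of chi2(df); mass outside is ~1e-12.
    lo = stats.chi2.ppf(1e-13, df)
    hi = stats.chi2.isf(1e-13, df)
    val, err = integrate.quad(integrand, lo, hi, limit=200, epsrel=_QUAD_RTOL)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise RuntimeError(
            f"Type M quadrature did not converge: value {val!r}, "
            f"abs error estimate {err!r}"
        )
    return float(val)


def analytic_type_m(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Exaggeration ratio E[|T| | |T| > t_crit] * sqrt(1/n1 + 1/n2) / |d|."""
    if d == 0:
        raise ValueError("Type M is undefined at d = 0")
    p = noncentral_params(abs(d), n1, n2, alpha)
    power = analytic_power(abs(d), n1, n2, alpha)
    scale = np.sqrt(1 / n1 + 1 / n2)
    return float(_e_abs_t_significant(p.df, p.ncp, p.t_crit) / power * scale / abs(d))
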