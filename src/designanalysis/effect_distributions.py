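"""Plausible effect sizes: point values and interval distributions.

A design analysis needs a *plausible* true effect, identified from theory or
meta-analysis rather than from a single noisy estimate. This module lets that
plausible effect be

* a point value of Cohen's *d*, or
* a probability distribution over a closed interval [lower, upper] — either
  uniform, or a doubly truncated normal centered on the interval midpoint
  whose standard deviation is a fraction of the interval length.

The default ``sd_fraction`` of 1/6 gives a normal-like shape with visible
mass near the bounds (greater uncertainty about the center); 1/10 gives a
distribution whose truncation is essentially cosmetic (the tails the bounds
cut off carry < 0.3% mass), i.e. "substantially normal".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "EffectSpec",
    "make_point_effect",
    "make_interval_effect",
    "sample_effects",
    "reference_effect",
    "truncated_normal",
]

_FAMILIES = ("uniform", "truncated_normal")


@dataclass(frozen=True)
class EffectSpec:
    """A plausible-effect specification: a point d or an interval distribution.

    Use :func:`make_point_effect` / :func:`make_interval_effect` instead of
    constructing directly.
    """

    kind: str  # "point" | "interval"
    d: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    family: Optional[str] = None
    sd_fraction: Optional[float] = None

    @property
    def center(self) -> float:
        """Midpoint of the interval (interval mode only)."""
        if self.kind != "interval":
            raise ValueError("center is defined only for interval-mode specs")
        return (self.lower + self.upper) / 2

    @property
    def sd(self) -> float:
        """Standard deviation of the untruncated normal (truncated_normal only)."""
        if self.family != "truncated_normal":
            raise ValueError("sd is defined only for truncated_normal specs")
        return self.sd_fraction * (self.upper - self.lower)

    def describe(self) -> str:
        if self.kind == "point":
            return f"point effect d = {self.d:g}"
        if self.family == "uniform":
            return f"uniform effect on [{self.lower:g}, {self.upper:g}]"
        return (
            f"truncated normal effect on [{self.lower:g}, {self.upper:g}], "
            f"mean {self.center:g}, sd {self.sd:g}"
        )


def make_point_effect(d: float) -> EffectSpec:
    """Spec for a single plausible Cohen's *d*.

    ``d = 0`` is allowed (it is the null, used for alpha-calibration checks)
    but Type M / Type S are undefined there.
    """
    if not np.isfinite(d):
        raise ValueError(f"point effect d must be finite, got {d!r}")
    return EffectSpec(kind="point", d=float(d))


def make_interval_effect(
    lower: float,
    upper: float,
    family: str = "truncated_normal",
    sd_fraction: float = 1.0 / 6.0,
) -> EffectSpec:
    """Spec for a plausible effect varying over [lower, upper].

    ``family="uniform"`` treats every value in the interval as equally
    plausible. ``family="truncated_normal"`` concentrates plausibility around
    the midpoint: a normal with mean at the center and standard deviation
    ``sd_fraction * (upper - lower)``, doubly truncated to the interval.
    """
    if not (np.isfinite(lower) and np.isfinite(upper) and lower < upper):
        raise ValueError(f"need lower < upper, got [{lower!r}, {upper!r}]")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    if family == "truncated_normal":
        if not (np.isfinite(sd_fraction) and sd_fraction > 0):
            raise ValueError(f"sd_fraction must be positive, got {sd_fraction!r}")
    else:
        sd_fraction = None
    return EffectSpec(
        kind="interval",
        lower=float(lower),
        upper=float(upper),
        family=family,
        sd_fraction=sd_fraction,
    )


def reference_effect(spec: EffectSpec) -> float:
    """The single d used as Type M denominator and Type S sign reference.

    Point mode: the point value. Interval mode: the interval center — the
    most plausible effect size, so "Type M = 1.7" reads as 70% expected
    overestimation of the most plausible effect.
    """
    return spec.d if spec.kind == "point" else spec.center


def truncated_normal(spec: EffectSpec) -> stats.rv_continuous:
    """Frozen scipy distribution of a truncated_normal spec."""
    if spec.family != "truncated_normal":
        raise ValueError("spec is not a truncated_normal interval spec")
    mu, sd = spec.center, spec.sd
    a, b = (spec.lower - mu) / sd, (spec.upper - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def sample_effects(spec: EffectSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` true effects from the spec.

    Point mode returns a constant vector. Interval draws go through the
    inverse CDF (a uniform draw mapped through the quantile function), which
    guarantees every draw lies inside [lower, upper] at fixed cost per draw.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if spec.kind == "point":
        return np.full(k, spec.d)
    u = rng.uniform(size=k)
    if spec.family == "uniform":
        return spec.lower + u * (spec.upper - spec.lower)
    return truncated_normal(spec).ppf(u)
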