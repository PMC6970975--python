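"""Reduce a simulated ensemble to power, Type M and Type S errors.

* **Power** — fraction of replicates reaching two-tailed significance.
* **Type M error (exaggeration ratio)** — mean of |d_obs| over the
  significant replicates, divided by the plausible effect. A value of 3
  means a significant finding is expected to triple the plausible effect.
* **Type S error (sign error)** — fraction of significant replicates whose
  estimate has the opposite sign to the plausible effect.

Type M and Type S condition on significance, so in a design with essentially
zero power they are undefined rather than zero: that case is reported with
explicit ``None`` sentinels and ``n_significant = 0``, never silently as 0 or
NaN — designs too weak to ever reach significance are precisely the ones
these metrics exist to flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .effect_distributions import EffectSpec, reference_effect
from .simulation_engine import DesignConfig, ReplicateSet

__all__ = [
    "DesignResult",
    "compute_power",
    "compute_type_m",
    "compute_type_s",
    "summarize",
]


@dataclass(frozen=True)
class DesignResult:
    """Power, Type M and Type S with Monte-Carlo standard errors.

    ``type_m``/``type_s`` are ``None`` when no replicate was significant.
    ``reference_d`` is the Type M denominator and Type S sign reference: the
    point effect, or the interval center in distribution mode.
    """

    power: float
    type_m: Optional[float]
    type_s: Optional[float]
    mc_se_power: float
    mc_se_type_m: Optional[float]
    mc_se_type_s: Optional[float]
    n_significant: int
    reference_d: float
    n1: int
    n2: int
    spec: EffectSpec
    config: DesignConfig

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "typeS": self.type_s,
            "typeM": self.type_m,
            "mc_se_power": self.mc_se_power,
            "mc_se_typeM": self.mc_se_type_m,
            "mc_se_typeS": self.mc_se_type_s,
            "n_significant": self.n_significant,
            "reference_d": self.reference_d,
            "n1": self.n1,
            "n2": self.n2,
            "alpha": self.config.alpha,
            "n_sims": self.config.n_sims,
            "seed": self.config.seed,
            "effect": self.spec.describe(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """One-row table mirroring the report column order power/typeS/typeM."""
        return pd.DataFrame(
            [
                {
                    "power": self.power,
                    "typeS": self.type_s,
                    "typeM": self.type_m,
                    "n1": self.n1,
                    "n2": self.n2,
                    "alpha": self.config.alpha,
                    "n_sims": self.config.n_sims,
                    "seed": self.config.seed,
                }
            ]
        )

    def report(self) -> str:
        """Human-readable two-decimal summary (full precision is retained
        on the object; rounding happens only here)."""
        ts = "undefined" if self.type_s is None else f"{self.type_s:.2f}"
        tm = "undefined" if self.type_m is None else f"{self.type_m:.2f}"
        lines = [
            f"Design analysis ({self.spec.describe()}; "
            f"n1 = {self.n1}, n2 = {self.n2}, alpha = {self.config.alpha:g}, "
            f"{self.config.n_sims} simulations, seed {self.config.seed})",
            " power typeS typeM",
            f" {self.power:5.2f} {ts:>5s} {tm:>5s}",
        ]
        if self.n_significant == 0:
            lines.append(
                " no replicate reached significance: Type M and Type S are "
                "undefined (the design cannot detect the plausible effect)"
            )
        return "\n".join(lines)


def compute_power(reps: ReplicateSet) -> float:
    """Fraction of replicates with a significant two-tailed test."""
    return float(np.mean(reps.significant))


def _sig_abs_d(reps: ReplicateSet) -> np.ndarray:
    return np.abs(reps.d_obs[reps.significant])


def compute_type_m(reps: ReplicateSet, reference_d: float) -> Optional[float]:
    """Exaggeration ratio: mean |d_obs| among significant replicates over
    |reference_d|. ``None`` when nothing was significant."""
    if reference_d == 0:
        raise ValueError("Type M is undefined for a zero reference effect")
    sig = _sig_abs_d(reps)
    if sig.size == 0:
        return None
    return float(sig.mean() / abs(reference_d))


def compute_type_s(reps: ReplicateSet, reference_d: float) -> Optional[float]:
    """Fraction of significant replicates with the wrong sign.

    "Wrong" is relative to ``sign(reference_d)``. ``None`` when nothing was
    significant.
    """
    if reference_d == 0:
        raise ValueError("Type S is undefined for a zero reference effect")
    sig_d = reps.d_obs[reps.significant]
    if sig_d.size == 0:
        return None
    wrong = (sig_d * np.sign(reference_d)) < 0
    return float(wrong.mean())


def summarize(reps: ReplicateSet) -> DesignResult:
    """Bundle the three metrics with Monte-Carlo standard errors.

    mc_se_power = sqrt(p (1-p) / n_sims); the Type M SE is the standard error
    of the conditional mean of |d_obs| scaled by the reference; the Type S SE
    is binomial over the significant count.
    """
    ref = reference_effect(reps.spec)
    p = compute_power(reps)
    n_sims = len(reps)
    sig = _sig_abs_d(reps)
    n_sig = int(sig.size)
    if n_sig > 0 and ref != 0:
        tm = compute_type_m(reps, ref)
        ts = compute_type_s(reps, ref)
        se_tm = float(sig.std(ddof=1) / np.sqrt(n_sig) / abs(ref)) if n_sig > 1 else None
        se_ts = float(np.sqrt(ts * (1 - ts) / n_sig))
    else:
        tm = ts = se_tm = se_ts = None
    return DesignResult(
        power=p,
        type_m=tm,
        type_s=ts,
        mc_se_power=float(np.sqrt(p * (1 - p) / n_sims)),
        mc_se_type_m=se_tm,
        mc_se_type_s=se_ts,
        n_significant=n_sig,
        reference_d=float(ref),
        n1=reps.n1,
        n2=reps.n2,
        spec=reps.spec,
        config=reps.config,
    )
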