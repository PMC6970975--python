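"""Built-in worked scenarios and programmatic test inputs.

Every scenario here is a fully specified design analysis — effect spec,
sample sizes (or a power target), alpha — together with its expected
headline numbers and a tolerance class:

* ``exact2dp`` — deterministic quantities (Cohen's d, critical d, df),
  compared at two printed decimals;
* ``mc`` — simulated quantities (power, Type M, Type S), compared within
  ``max(0.01, 4 * Monte-Carlo SE)`` at the configured replicate count;
* ``n_pm2`` — searched sample sizes, compared within ±2 (simulation-based
  searches scatter a step around the exact crossing of a flat power curve).

The registry doubles as a regression suite and as runnable examples
(``designanalysis fixtures list`` / ``fixtures run NAME``). A reduced
replicate profile (20,000 simulations) keeps full-registry runs fast; the
``mc`` tolerance automatically widens with the larger Monte-Carlo SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design_metrics import DesignResult, summarize
from .effect_distributions import (
    EffectSpec,
    make_interval_effect,
    make_point_effect,
)
from .planning import prospective_design, retrospective_design
from .simulation_engine import DesignConfig, run_simulation
from .stats_core import GroupSummary, cohens_d, critical_d

__all__ = [
    "Expectation",
    "ScenarioFixture",
    "ScenarioOutcome",
    "builtin_scenarios",
    "get_scenario",
    "run_scenario",
    "make_group_fixture",
    "cognitive_treatment_groups",
    "test_profile",
]

_TOL_CLASSES = ("exact2dp", "mc", "n_pm2")


@dataclass(frozen=True)
class Expectation:
    """An expected metric value with its tolerance class."""

    value: float
    tol_class: str

    def __post_init__(self) -> None:
        if self.tol_class not in _TOL_CLASSES:
            raise ValueError(f"unknown tolerance class {self.tol_class!r}")


@dataclass(frozen=True)
class ScenarioFixture:
    """A named, self-contained design-analysis scenario with expected output.

    ``mode`` is "retrospective" (fixed n1/n2) or "prospective" (balanced
    search at ``target_power``). ``expected`` maps metric names — power,
    type_m, type_s, n_per_group, critical_d — to :class:`Expectation`.
    """

    name: str
    label: str
    mode: str
    spec: EffectSpec
    config: DesignConfig
    expected: dict
    n1: Optional[int] = None
    n2: Optional[int] = None
    target_power: Optional[float] = None


@dataclass(frozen=True)
class CheckedMetric:
    metric: str
    observed: float
    expected: float
    tolerance: float
    ok: bool


@dataclass(frozen=True)
class ScenarioOutcome:
    scenario: ScenarioFixture
    result: Optional[DesignResult]
    checks: tuple

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)

    def report(self) -> str:
        lines = [f"scenario {self.scenario.name}: {self.scenario.label}"]
        for c in self.checks:
            status = "ok" if c.ok else "FAIL"
            lines.append(
                f"  {c.metric:12s} observed {c.observed:8.4f}  "
                f"expected {c.expected:8.4f}  tol {c.tolerance:.4f}  {status}"
            )
        return "\n".join(lines)


def test_profile(seed: int = 7, n_sims: int = 20_000) -> DesignConfig:
    """Reduced-replicate configuration for fast full-registry runs."""
    return DesignConfig(n_sims=n_sims, seed=seed)


def _mc(v: float) -> Expectation:
    return Expectation(v, "mc")


def builtin_scenarios() -> tuple[ScenarioFixture, ...]:
    """The registry of worked design-analysis scenarios.

    Expected values are the two-decimal numbers each analysis prints under
    its stated inputs; they are reproduced by simulation at any adequate
    replicate count via the ``mc`` tolerance rule.
    """
    cfg = DesignConfig()
    scenarios = [
        ScenarioFixture(
            name="winners_curse_small_effect",
            label=(
                "underpowered two-group study of a small effect (d=0.20, "
                "33 per group): only inflated estimates can reach significance"
            ),
            mode="retrospective",
            spec=make_point_effect(0.20),
            config=cfg,
            n1=33,
            n2=33,
            expected={
                "power": _mc(0.13),
                "type_m": _mc(3.11),
                "type_s": _mc(0.02),
                "critical_d": Expectation(0.49, "exact2dp"),
            },
        ),
        ScenarioFixture(
            name="prospective_d025_power80",
            label="plan a balanced study for d=0.25 at 80% power",
            mode="prospective",
            spec=make_point_effect(0.25),
            config=cfg,
            target_power=0.80,
            expected={
                "n_per_group": Expectation(252, "n_pm2"),
                "type_m": _mc(1.13),
                "type_s": _mc(0.00),
            },
        ),
        ScenarioFixture(
            name="prospective_d025_power60",
            label="plan a balanced study for d=0.25 at 60% power",
            mode="prospective",
            spec=make_point_effect(0.25),
            config=cfg,
            target_power=0.60,
            expected={
                "n_per_group": Expectation(158, "n_pm2"),
                "type_m": _mc(1.30),
            },
        ),
        ScenarioFixture(
            name="retrospective_d025_31pp",
            label=(
                "risk evaluation of a completed 31-per-group trial under a "
                "plausible d of 0.25"
            ),
            mode="retrospective",
            spec=make_point_effect(0.25),
            config=cfg,
            n1=31,
            n2=31,
            expected={
                "power": _mc(0.16),
                "type_s": _mc(0.01),
                "type_m": _mc(2.59),
            },
        ),
        ScenarioFixture(
            name="interval_truncnorm_31pp",
            label=(
                "distribution-mode evaluation at 31 per group: plausible d on "
                "[0.20, 0.60], truncated normal, sd = interval/6"
            ),
            mode="retrospective",
            spec=make_interval_effect(0.20, 0.60, "truncated_normal", 1 / 6),
            config=cfg,
            n1=31,
            n2=31,
            expected={
                "power": _mc(0.35),
                "type_s": _mc(0.00),
                "type_m": _mc(1.73),
            },
        ),
        ScenarioFixture(
            name="case_study_d020",
            label="published study re-analysis (total n=67 split 33/34), d=0.20",
            mode="retrospective",
            spec=make_point_effect(0.20),
            config=cfg,
            n1=33,
            n2=34,
            expected={
                "power": _mc(0.13),
                "type_m": _mc(3.06),
                "type_s": _mc(0.02),
            },
        ),
        ScenarioFixture(
            name="case_study_d035",
            label="published study re-analysis (33/34), d=0.35",
            mode="retrospective",
            spec=make_point_effect(0.35),
            config=cfg,
            n1=33,
            n2=34,
            expected={
                "power": _mc(0.29),
                "type_m": _mc(1.86),
                "type_s": _mc(0.00),
            },
        ),
        ScenarioFixture(
            name="case_study_d050",
            label="published study re-analysis (33/34), d=0.50",
            mode="retrospective",
            spec=make_point_effect(0.50),
            config=cfg,
            n1=33,
            n2=34,
            expected={
                "power": _mc(0.52),
                "type_m": _mc(1.40),
            },
        ),
    ]
    # Planning-table cells: (d, target power) -> printed per-group n.
    for d, power, n in [
        (0.20, 0.80, 392),
        (0.35, 0.80, 130),
        (0.50, 0.80, 64),
        (0.20, 0.60, 244),
        (0.35, 0.60, 82),
        (0.50, 0.60, 40),
    ]:
        scenarios.append(
            ScenarioFixture(
                name=f"plan_table_d{int(d * 100):03d}_p{int(power * 100)}",
                label=f"planning-table cell d={d:.2f}, power={power:.2f}",
                mode="prospective",
                spec=make_point_effect(d),
                config=cfg,
                target_power=power,
                expected={"n_per_group": Expectation(n, "n_pm2")},
            )
        )
    return tuple(scenarios)


def get_scenario(name: str) -> ScenarioFixture:
    for sc in builtin_scenarios():
        if sc.name == name:
            return sc
    raise KeyError(f"no builtin scenario named {name!r}")


def _mc_tolerance(metric: str, result: Optional[DesignResult]) -> float:
    floor = 0.01
    if result is None:
        return floor
    se = {
        "power": result.mc_se_power,
        "type_m": result.mc_se_type_m,
        "type_s": result.mc_se_type_s,
    }.get(metric)
    return max(floor, 4 * se) if se is not None else floor


def run_scenario(
    sc: ScenarioFixture, config: Optional[DesignConfig] = None
) -> ScenarioOutcome:
    """Execute a scenario and compare each metric to its expected value.

    ``config`` overrides the scenario's replicate count / seed (e.g. the
    reduced test profile); tolerances adapt to the actual Monte-Carlo SE.
    """
    cfg = config if config is not None else sc.config
    if sc.mode == "retrospective":
        result = retrospective_design(sc.n1, sc.n2, sc.spec, cfg)
        observed = {
            "power": result.power,
            "type_m": result.type_m,
            "type_s": result.type_s,
            "critical_d": critical_d(sc.n1, sc.n2, cfg.alpha),
        }
    elif sc.mode == "prospective":
        plan = prospective_design(sc.spec, sc.target_power, cfg)
        result = plan.result
        observed = {
            "power": result.power,
            "type_m": plan.type_m,
            "type_s": plan.type_s,
            "n_per_group": plan.n_per_group,
        }
    else:  # pragma: no cover - registry is closed
        raise ValueError(f"unknown scenario mode {sc.mode!r}")

    checks = []
    for metric, exp in sc.expected.items():
        obs = observed[metric]
        if exp.tol_class == "exact2dp":
            tol = 0.005
        elif exp.tol_class == "n_pm2":
            tol = 2.0
        else:
            tol = _mc_tolerance(metric, result)
        ok = obs is not None and abs(obs - exp.value) <= tol
        checks.append(
            CheckedMetric(
                metric=metric,
                observed=float("nan") if obs is None else float(obs),
                expected=exp.value,
                tolerance=tol,
                ok=bool(ok),
            )
        )
    return ScenarioOutcome(scenario=sc, result=result, checks=tuple(checks))


def make_group_fixture(
    seed: int, d_true: float, n: int
) -> tuple[GroupSummary, GroupSummary]:
    """Summaries of one simulated two-group dataset at a given true d.

    Group 1 ~ N(d_true, 1), group 2 ~ N(0, 1), n per group; deterministic in
    the seed. Useful as a synthetic observed study for the effect-size API.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    y1 = rng.standard_normal(n) + d_true
    y2 = rng.standard_normal(n)
    return (
        GroupSummary(n=n, mean=float(y1.mean()), sd=float(y1.std(ddof=1))),
        GroupSummary(n=n, mean=float(y2.mean()), sd=float(y2.std(ddof=1))),
    )


def cognitive_treatment_groups() -> tuple[GroupSummary, GroupSummary]:
    """The worked observed-study example: an innovative cognitive treatment
    (n=31, M=114, SD=16) against a traditional one (n=31, M=100, SD=15).

    Cohen's d is 0.90 with a wide 95% CI (0.38-1.43) — a textbook case where
    a single significant study overstates a plausibly small effect.
    """
    return (
        GroupSummary(n=31, mean=114.0, sd=16.0),
        GroupSummary(n=31, mean=100.0, sd=15.0),
    )
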