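"""One-way deterministic sensitivity analysis.

Each analysis moves one parameter group to its lower or upper bound —
the 95% CI bounds for epidemiological rates and the dose-response
relative risk, or 0%/4% for the discount rate — while everything else
stays at its point value, and reports the induced range in cumulative
discounted expenditure savings.  Rate perturbations substitute the
bound jointly across all age bands of a sex, and apply to the base-case
and intervention runs alike, so the interval isolates uncertainty in
the *savings* rather than in the epidemiology level.  Results are
reported per sex, matching the granularity of the underlying inputs.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .parameters import ModelConfig, ParameterSet, RateWithCI, Sex
from .pipeline import simulate
from .scenarios import SCENARIO_1, SCENARIO_2, ScenarioName, ScenarioSpec

__all__ = [
    "SensitivityParameter",
    "SensitivityResult",
    "one_way_sensitivity",
    "sensitivity_report",
]


class SensitivityParameter(str, enum.Enum):
    INCIDENCE = "incidence"
    PREVALENCE = "prevalence"
    STROKE_MORTALITY = "stroke_mortality"
    ALL_CAUSE_MORTALITY = "all_cause_mortality"
    RELATIVE_RISK = "relative_risk"
    DISCOUNT_RATE = "discount_rate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_RATE_FIELDS = {
    SensitivityParameter.INCIDENCE: "incidence",
    SensitivityParameter.PREVALENCE: "prevalence",
    SensitivityParameter.STROKE_MORTALITY: "stroke_mortality",
    SensitivityParameter.ALL_CAUSE_MORTALITY: "all_cause_mortality",
}

DISCOUNT_BOUNDS = (0.0, 0.04)


@dataclass(frozen=True)
class SensitivityResult:
    parameter: SensitivityParameter
    sex: Sex
    scenario: ScenarioName
    savings_lower_bound: float
    savings_upper_bound: float

    @property
    def interval_width(self) -> float:
        return self.savings_upper_bound - self.savings_lower_bound


def _perturb_rates(params: ParameterSet, field: str, which: str, sex: Sex) -> ParameterSet:
    """Substitute the ``which`` CI bound of ``field`` for every stratum of ``sex``."""
    new_strata = dict(params.strata)
    for stratum, sp in params.strata.items():
        if stratum.sex != sex:
            continue
        rate: RateWithCI = getattr(sp, field)
        new_rate = dataclasses.replace(rate, point=rate.at(which))
        new_strata[stratum] = dataclasses.replace(sp, **{field: new_rate})
    return params.replace(strata=new_strata)


def _savings(params: ParameterSet, spec: ScenarioSpec, config: ModelConfig, sex: Sex) -> float:
    result = simulate(params, scenarios=(spec,), config=config, strata=params.for_sex(sex))
    return result.nhe_savings(spec.name)


def one_way_sensitivity(
    params: ParameterSet,
    parameter: SensitivityParameter,
    scenario: ScenarioSpec,
    sex: Sex,
    config: Optional[ModelConfig] = None,
) -> SensitivityResult:
    """Savings bounds when ``parameter`` moves to its low/high setting.

    The bounds are re-oriented so lower <= upper regardless of which
    input bound produced which (e.g. the weaker relative risk, 0.90,
    yields the lower savings bound).
    """
    parameter = SensitivityParameter(parameter)
    cfg = config if config is not None else params.config
    if parameter in _RATE_FIELDS:
        field = _RATE_FIELDS[parameter]
        a = _savings(_perturb_rates(params, field, "lower", sex), scenario, cfg, sex)
        b = _savings(_perturb_rates(params, field, "upper", sex), scenario, cfg, sex)
    elif parameter is SensitivityParameter.RELATIVE_RISK:
        dose = params.dose
        a = _savings(
            params.replace(dose=dataclasses.replace(dose, rr_per_200g=dose.ci_upper)),
            scenario,
            cfg,
            sex,
        )
        b = _savings(
            params.replace(dose=dataclasses.replace(dose, rr_per_200g=dose.ci_lower)),
            scenario,
            cfg,
            sex,
        )
    elif parameter is SensitivityParameter.DISCOUNT_RATE:
        lo_cfg = dataclasses.replace(cfg, discount_rate=DISCOUNT_BOUNDS[0])
        hi_cfg = dataclasses.replace(cfg, discount_rate=DISCOUNT_BOUNDS[1])
        a = _savings(params, scenario, hi_cfg, sex)
        b = _savings(params, scenario, lo_cfg, sex)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown sensitivity parameter {parameter!r}")
    lower, upper = (a, b) if a <= b else (b, a)
    return SensitivityResult(parameter, sex, scenario.name, lower, upper)


def sensitivity_report(
    params: ParameterSet,
    scenarios: Sequence[ScenarioSpec] = (SCENARIO_1, SCENARIO_2),
    config: Optional[ModelConfig] = None,
) -> pd.DataFrame:
    """Full one-way matrix: one row per (parameter x sex x scenario).

    Within each sex and scenario, rows are ordered by interval width
    descending (tornado-style).
    """
    rows = []
    for spec in scenarios:
        for sex in (Sex.MEN, Sex.WOMEN):
            results = [
                one_way_sensitivity(params, p, spec, sex, config)
                for p in SensitivityParameter
            ]
            results.sort(key=lambda r: r.interval_width, reverse=True)
            for r in results:
                rows.append(
                    {
                        "scenario": r.scenario.value,
                        "sex": r.sex.value,
                        "parameter": r.parameter.value,
                        "lower_usd": r.savings_lower_bound,
                        "upper_usd": r.savings_upper_bound,
                        "width_usd": r.interval_width,
                    }
                )
    return pd.DataFrame(rows)
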