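"""Seedable synthetic parameter sets with the structure the model assumes.

The generator emulates the shape of the real inputs — ten sex x age
strata with age-increasing stroke and mortality rates, 95% CI bounds
bracketing each point value, sub-target dairy intakes, and positive
cost triplets roughly proportional to the population at risk — while
ranging deliberately wider than any national dataset so that caps,
validation and degenerate paths get exercised.  Every generated set
passes :func:`milkstroke.parameters.validate_parameter_set` by
construction, and a single integer seed fixes the full output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    AGE_BANDS,
    CostParameters,
    DoseResponse,
    ModelConfig,
    ParameterSet,
    RateWithCI,
    Sex,
    SexLevelParameters,
    Stratum,
    StratumParameters,
)

__all__ = ["GeneratorConfig", "generate_parameter_set", "generate_null_set"]

# Plausible national ranges, per 100,000; deliberately wide.
_INCIDENCE_RANGE = (20.0, 800.0)
_PREVALENCE_RANGE = (300.0, 10_000.0)
_STROKE_MORT_RANGE = (1.0, 300.0)
_ALL_CAUSE_CAP = 3_000.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_strata: int = 10
    rate_scale: float = 1.0
    ci_relative_width: float = 0.25
    cost_scale: float = 1.0


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _ci(point: float, width: float) -> RateWithCI:
    return RateWithCI(point=point, lower=point * (1 - width), upper=point * (1 + width))


def generate_parameter_set(config: GeneratorConfig) -> ParameterSet:
    """Draw a full, valid parameter set from the given seed."""
    if config.n_strata != len(AGE_BANDS) * 2:
        raise ValueError(
            f"a full parameter set has exactly {len(AGE_BANDS) * 2} strata, "
            f"got n_strata={config.n_strata}"
        )
    rng = np.random.default_rng(config.seed)
    w = config.ci_relative_width
    n = len(AGE_BANDS)

    strata: dict[Stratum, StratumParameters] = {}
    costs: dict[Stratum, CostParameters] = {}
    sex_level: dict[Sex, SexLevelParameters] = {}
    for sex in (Sex.MEN, Sex.WOMEN):
        # Age-increasing profiles: sorted log-uniform draws.
        inc = np.sort(_loguniform(rng, *_INCIDENCE_RANGE, n)) * config.rate_scale
        prev = np.sort(_loguniform(rng, *_PREVALENCE_RANGE, n)) * config.rate_scale
        smort = np.sort(_loguniform(rng, *_STROKE_MORT_RANGE, n)) * config.rate_scale
        # All-cause mortality at least twice stroke mortality, capped.
        acm = smort * rng.uniform(2.0, 8.0, n)
        acm = np.minimum(np.maximum.accumulate(acm), _ALL_CAUSE_CAP * config.rate_scale)
        acm = np.maximum(acm, 2.0 * smort)
        prev = np.minimum(prev, 99_000.0)
        pop = rng.uniform(2e6, 12e6, n)
        intake = rng.uniform(40.0, 170.0, n)

        for i, band in enumerate(AGE_BANDS):
            stratum = Stratum(sex, band)
            strata[stratum] = StratumParameters(
                stratum=stratum,
                population=float(pop[i]),
                dairy_intake_mean=float(intake[i]),
                incidence=_ci(float(inc[i]), w),
                prevalence=_ci(float(prev[i]), w),
                stroke_mortality=_ci(float(smort[i]), w),
                all_cause_mortality=_ci(float(acm[i]), w),
            )
            # Costs roughly proportional to the population at risk.
            events = pop[i] * inc[i] / 1e5
            chronic = pop[i] * prev[i] / 1e5
            costs[stratum] = CostParameters(
                stratum=stratum,
                inpatient_annual=float(
                    events * _loguniform(rng, 2e3, 2e4, 1)[0] * config.cost_scale
                ),
                outpatient_annual=float(
                    chronic * _loguniform(rng, 50.0, 500.0, 1)[0] * config.cost_scale
                ),
                drug_annual=float(
                    chronic * _loguniform(rng, 50.0, 500.0, 1)[0] * config.cost_scale
                ),
            )
        sex_level[sex] = SexLevelParameters(
            fatality_28day=float(rng.uniform(0.10, 0.20)),
            recurrence_rate=float(rng.uniform(0.15, 0.35)),
        )

    rr = float(rng.uniform(0.70, 0.95))
    dose = DoseResponse(
        rr_per_200g=rr, ci_lower=rr * 0.9, ci_upper=min(rr * 1.1, 1.0), reference_dose=200.0
    )
    return ParameterSet(
        strata=strata,
        sex_level=sex_level,
        dose=dose,
        costs=costs,
        config=ModelConfig(),
    )


def generate_null_set(config: GeneratorConfig) -> ParameterSet:
    """A synthetic set whose dose response is null (RR = 1).

    The full pipeline must then yield zero prevented cases, deaths and
    savings under every scenario.
    """
    pset = generate_parameter_set(config)
    return pset.replace(dose=DoseResponse(rr_per_200g=1.0, ci_lower=1.0, ci_upper=1.0))
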