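"""Model inputs: domain types, validation, and tabular IO.

All epidemiological rates are stored exactly as published (events per
100,000 person-years, or per 100,000 persons for prevalence); conversion
to transition probabilities happens in :mod:`milkstroke.markov`.  This
keeps parameter files directly auditable against their sources.

A parameter file is a flat, diffable text format: a block of
``# key: value`` header lines carrying the sex-level and scalar
parameters, followed by a CSV table with one row per sex x age-band
stratum.  The 2023 Japanese baseline shipped with the package is
available as the built-in fixture name ``"paper2023"``.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "Sex",
    "AGE_BANDS",
    "Stratum",
    "RateWithCI",
    "StratumParameters",
    "SexLevelParameters",
    "DoseResponse",
    "CostParameters",
    "ModelConfig",
    "ParameterSet",
    "Violation",
    "SchemaError",
    "ValidationError",
    "load_parameter_set",
    "write_parameter_set",
    "validate_parameter_set",
    "jpy_to_usd",
]


class Sex(str, enum.Enum):
    MEN = "men"
    WOMEN = "women"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ten-year age bands covering ages 30-79, the population modelled.
AGE_BANDS: tuple[str, ...] = ("30-39", "40-49", "50-59", "60-69", "70-79")


@dataclass(frozen=True, order=True)
class Stratum:
    """One sex x 10-year-age-band cell of the stratified cohort."""

    sex: Sex
    age_band: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise SchemaError(f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}")

    @property
    def label(self) -> str:
        return f"{self.sex.value} {self.age_band}"


#: The full cross of sexes and age bands; a complete parameter set has
#: exactly these ten strata.
ALL_STRATA: tuple[Stratum, ...] = tuple(
    Stratum(sex, band) for sex in (Sex.MEN, Sex.WOMEN) for band in AGE_BANDS
)


@dataclass(frozen=True)
class RateWithCI:
    """A point rate with its 95% confidence bounds (same units)."""

    point: float
    lower: float
    upper: float

    def at(self, which: str) -> float:
        """Return the ``"point"``, ``"lower"`` or ``"upper"`` value."""
        return {"point": self.point, "lower": self.lower, "upper": self.upper}[which]


@dataclass(frozen=True)
class StratumParameters:
    """Epidemiology, intake and population for one stratum.

    Rates are per 100,000 person-years except ``prevalence`` (per
    100,000 persons).  ``dairy_intake_mean`` is the 2023 mean dairy
    product intake in g/day, the baseline the milk intervention is
    measured against.
    """

    stratum: Stratum
    population: float
    dairy_intake_mean: float
    incidence: RateWithCI
    prevalence: RateWithCI
    stroke_mortality: RateWithCI
    all_cause_mortality: RateWithCI


@dataclass(frozen=True)
class SexLevelParameters:
    """Parameters available only by sex, not by age band.

    ``fatality_28day`` is the probability that a stroke event (first or
    recurrent) is fatal within the 28-day acute phase.  ``recurrence_rate``
    is the per-cycle probability of a recurrent stroke among chronic
    survivors, constant regardless of the number of prior events.
    """

    fatality_28day: float
    recurrence_rate: float


@dataclass(frozen=True)
class DoseResponse:
    """Relative risk of stroke per ``reference_dose`` g/day of milk."""

    rr_per_200g: float = 0.82
    ci_lower: float = 0.75
    ci_upper: float = 0.90
    reference_dose: float = 200.0


@dataclass(frozen=True)
class CostParameters:
    """Annual aggregate national healthcare expenditure for one stratum (USD)."""

    stratum: Stratum
    inpatient_annual: float
    outpatient_annual: float
    drug_annual: float


@dataclass(frozen=True)
class ModelConfig:
    """Simulation-wide settings.

    ``exchange_rate_jpy_per_usd`` is metadata: bundled costs are already
    in USD; it is exposed for users converting their own JPY inputs via
    :func:`jpy_to_usd`.
    """

    horizon_cycles: int = 10
    cycle_length: float = 1.0
    target_intake: float = 180.0
    discount_rate: float = 0.02
    exchange_rate_jpy_per_usd: float = 156.65


@dataclass(frozen=True)
class ParameterSet:
    """A complete, simulation-ready collection of model inputs."""

    strata: Mapping[Stratum, StratumParameters]
    sex_level: Mapping[Sex, SexLevelParameters]
    dose: DoseResponse
    costs: Mapping[Stratum, CostParameters]
    config: ModelConfig = field(default_factory=ModelConfig)

    def for_sex(self, sex: Sex) -> tuple[Stratum, ...]:
        return tuple(s for s in self.strata if s.sex == sex)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)


class SchemaError(ValueError):
    """A parameter source is structurally incomplete or malformed."""


class ValidationError(ValueError):
    """A structurally complete parameter set violates a model invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


@dataclass(frozen=True)
class Violation:
    """One violated invariant, as data rather than an exception."""

    stratum: str  # stratum label, sex, or "(global)"
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.stratum}: {self.field}: {self.rule}"


def _check_ci(label: str, name: str, rate: RateWithCI, out: list[Violation]) -> None:
    if not (0 <= rate.lower <= rate.point <= rate.upper):
        out.append(Violation(label, name, "requires 0 <= lower <= point <= upper"))


def validate_parameter_set(params: ParameterSet) -> list[Violation]:
    """Return every violated invariant; an empty list means simulation may proceed."""
    out: list[Violation] = []
    missing = [s for s in ALL_STRATA if s not in params.strata]
    for s in missing:
        out.append(Violation(s.label, "strata", "stratum missing from parameter set"))
    for stratum, p in params.strata.items():
        label = stratum.label
        if not p.population > 0:
            out.append(Violation(label, "population", "must be > 0"))
        if not p.dairy_intake_mean > 0:
            out.append(Violation(label, "dairy_intake_mean", "must be > 0"))
        for name in ("incidence", "prevalence", "stroke_mortality", "all_cause_mortality"):
            _check_ci(label, name, getattr(p, name), out)
        if p.stroke_mortality.point > p.all_cause_mortality.point:
            out.append(
                Violation(
                    label,
                    "stroke_mortality",
                    "stroke mortality point exceeds all-cause mortality point",
                )
            )
        if not p.prevalence.point < 100_000:
            out.append(Violation(label, "prevalence", "must be < 100,000 per 100,000"))
    for sex, sp in params.sex_level.items():
        for name in ("fatality_28day", "recurrence_rate"):
            v = getattr(sp, name)
            if not (0 < v < 1):
                out.append(Violation(sex.value, name, "must lie in (0, 1)"))
    d = params.dose
    if not (0 < d.ci_lower <= d.rr_per_200g <= d.ci_upper):
        out.append(Violation("(global)", "dose_response", "requires 0 < ci_lower <= rr <= ci_upper"))
    for stratum, c in params.costs.items():
        for name in ("inpatient_annual", "outpatient_annual", "drug_annual"):
            if getattr(c, name) < 0:
                out.append(Violation(stratum.label, name, "must be >= 0"))
    cfg = params.config
    if cfg.horizon_cycles < 1:
        out.append(Violation("(global)", "horizon_cycles", "must be >= 1"))
    if not (0 <= cfg.discount_rate <= 1):
        out.append(Violation("(global)", "discount_rate", "must lie in [0, 1]"))
    return out


# ---------------------------------------------------------------------------
# Tabular IO

_COLUMNS = [
    "sex",
    "age_band",
    "population",
    "dairy_g_day",
    "incidence",
    "incidence_lo",
    "incidence_hi",
    "prevalence",
    "prevalence_lo",
    "prevalence_hi",
    "stroke_mort",
    "stroke_mort_lo",
    "stroke_mort_hi",
    "allcause_mort",
    "allcause_mort_lo",
    "allcause_mort_hi",
    "inpatient_usd",
    "outpatient_usd",
    "drug_usd",
]

_SCALAR_KEYS = {
    "fatality_28day_men": ("sex_level", Sex.MEN, "fatality_28day"),
    "fatality_28day_women": ("sex_level", Sex.WOMEN, "fatality_28day"),
    "recurrence_rate_men": ("sex_level", Sex.MEN, "recurrence_rate"),
    "recurrence_rate_women": ("sex_level", Sex.WOMEN, "recurrence_rate"),
    "rr_per_200g": ("dose", None, "rr_per_200g"),
    "rr_ci_lower": ("dose", None, "ci_lower"),
    "rr_ci_upper": ("dose", None, "ci_upper"),
    "reference_dose_g": ("dose", None, "reference_dose"),
    "horizon_cycles": ("config", None, "horizon_cycles"),
    "cycle_length_years": ("config", None, "cycle_length"),
    "target_intake_g_day": ("config", None, "target_intake"),
    "discount_rate": ("config", None, "discount_rate"),
    "exchange_rate_jpy_per_usd": ("config", None, "exchange_rate_jpy_per_usd"),
}


def _fixture_path(name: str) -> Path:
    ref = resources.files("milkstroke") / "data" / f"{name}.csv"
    with resources.as_file(ref) as p:
        return Path(p)


def load_parameter_set(source: Union[str, Path]) -> ParameterSet:
    """Read and validate a full parameter set.

    ``source`` is either a built-in fixture name (``"paper2023"``, the
    2023 Japanese baseline) or the path of a parameter file written by
    :func:`write_parameter_set`.

    Raises :class:`SchemaError` when strata or columns are missing and
    :class:`ValidationError` when a model invariant is violated.
    """
    path = Path(source)
    if not path.exists():
        if isinstance(source, str) and "/" not in source and not str(source).endswith(".csv"):
            try:
                path = _fixture_path(source)
            except FileNotFoundError:
                raise SchemaError(f"unknown parameter source {source!r}") from None
        if not path.exists():
            raise SchemaError(f"parameter source {source!r} does not exist")

    scalars: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in _SCALAR_KEYS:
                    scalars[key] = float(val.strip())
    missing_keys = sorted(set(_SCALAR_KEYS) - set(scalars))
    if missing_keys:
        raise SchemaError(f"missing header parameter(s): {', '.join(missing_keys)}")

    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in _COLUMNS if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s): {', '.join(missing_cols)}")

    strata: dict[Stratum, StratumParameters] = {}
    costs: dict[Stratum, CostParameters] = {}
    for _, row in table.iterrows():
        try:
            sex = Sex(str(row["sex"]).strip().lower())
        except ValueError:
            raise SchemaError(f"unknown sex {row['sex']!r}") from None
        stratum = Stratum(sex, str(row["age_band"]).strip())
        strata[stratum] = StratumParameters(
            stratum=stratum,
            population=float(row["population"]),
            dairy_intake_mean=float(row["dairy_g_day"]),
            incidence=RateWithCI(row["incidence"], row["incidence_lo"], row["incidence_hi"]),
            prevalence=RateWithCI(row["prevalence"], row["prevalence_lo"], row["prevalence_hi"]),
            stroke_mortality=RateWithCI(
                row["stroke_mort"], row["stroke_mort_lo"], row["stroke_mort_hi"]
            ),
            all_cause_mortality=RateWithCI(
                row["allcause_mort"], row["allcause_mort_lo"], row["allcause_mort_hi"]
            ),
        )
        costs[stratum] = CostParameters(
            stratum=stratum,
            inpatient_annual=float(row["inpatient_usd"]),
            outpatient_annual=float(row["outpatient_usd"]),
            drug_annual=float(row["drug_usd"]),
        )

    absent = [s.label for s in ALL_STRATA if s not in strata]
    if absent:
        raise SchemaError(f"missing stratum row(s): {', '.join(absent)}")

    pset = ParameterSet(
        strata=strata,
        sex_level={
            Sex.MEN: SexLevelParameters(
                scalars["fatality_28day_men"], scalars["recurrence_rate_men"]
            ),
            Sex.WOMEN: SexLevelParameters(
                scalars["fatality_28day_women"], scalars["recurrence_rate_women"]
            ),
        },
        dose=DoseResponse(
            rr_per_200g=scalars["rr_per_200g"],
            ci_lower=scalars["rr_ci_lower"],
            ci_upper=scalars["rr_ci_upper"],
            reference_dose=scalars["reference_dose_g"],
        ),
        costs=costs,
        config=ModelConfig(
            horizon_cycles=int(scalars["horizon_cycles"]),
            cycle_length=scalars["cycle_length_years"],
            target_intake=scalars["target_intake_g_day"],
            discount_rate=scalars["discount_rate"],
            exchange_rate_jpy_per_usd=scalars["exchange_rate_jpy_per_usd"],
        ),
    )
    violations = validate_parameter_set(pset)
    if violations:
        raise ValidationError(violations)
    return pset


def write_parameter_set(params: ParameterSet, path: Union[str, Path]) -> None:
    """Write ``params`` in the flat header+CSV format read by :func:`load_parameter_set`.

    Numbers are written with ``repr`` so a round-trip reproduces every
    field bit-exactly.
    """
    cfg, dose = params.config, params.dose
    men, women = params.sex_level[Sex.MEN], params.sex_level[Sex.WOMEN]
    header_values = {
        "fatality_28day_men": men.fatality_28day,
        "fatality_28day_women": women.fatality_28day,
        "recurrence_rate_men": men.recurrence_rate,
        "recurrence_rate_women": women.recurrence_rate,
        "rr_per_200g": dose.rr_per_200g,
        "rr_ci_lower": dose.ci_lower,
        "rr_ci_upper": dose.ci_upper,
        "reference_dose_g": dose.reference_dose,
        "horizon_cycles": cfg.horizon_cycles,
        "cycle_length_years": cfg.cycle_length,
        "target_intake_g_day": cfg.target_intake,
        "discount_rate": cfg.discount_rate,
        "exchange_rate_jpy_per_usd": cfg.exchange_rate_jpy_per_usd,
    }
    lines = ["# milkstroke parameter set"]
    lines += [f"# {k}: {v!r}" for k, v in header_values.items()]
    lines.append(",".join(_COLUMNS))
    for stratum in sorted(params.strata, key=lambda s: (s.sex.value, s.age_band)):
        p = params.strata[stratum]
        c = params.costs[stratum]
        row = [
            stratum.sex.value,
            stratum.age_band,
            repr(p.population),
            repr(p.dairy_intake_mean),
        ]
        for rate in (p.incidence, p.prevalence, p.stroke_mortality, p.all_cause_mortality):
            row += [repr(rate.point), repr(rate.lower), repr(rate.upper)]
        row += [repr(c.inpatient_annual), repr(c.outpatient_annual), repr(c.drug_annual)]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def jpy_to_usd(amount_jpy: float, config: ModelConfig = ModelConfig()) -> float:
    """Convert a JPY amount to USD at the configured exchange rate."""
    return amount_jpy / config.exchange_rate_jpy_per_usd
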