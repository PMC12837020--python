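"""Declarative model specification: schema, validation, (de)serialization.

The whole cost-of-illness model is driven by a single parameter file
(YAML or JSON) that encodes the population cascade, the per-grade
treatment protocols with their unit costs, adverse-event expectations,
supportive-care eligibility, productivity assumptions and economy-wide
scalars.  The bundled ``ksa_2024.yaml`` carries the Saudi 2024
parameterization; :func:`generate_scenario <visioncost.synth.generate_scenario>`
produces random but structurally valid instances of the same schema.

Severity grading follows the Scottish diabetic-retinopathy system:
R1 (mild non-proliferative) through R4 (proliferative) plus maculopathy
grades M1/M2, with blindness carried as its own ``BLIND`` grade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Annotated, Dict, List, Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = 1

GradeCode = Literal["R1", "R2", "R3", "R4", "M1", "M2", "BLIND"]
SeverityClass = Literal["mild", "moderate", "severe", "sight_threatening", "blind"]

#: Retinopathy/maculopathy grades subject to the overlap correction factor.
RM_GRADES: tuple[str, ...] = ("R1", "R2", "R3", "R4", "M1", "M2")
#: Canonical reporting order for all grades.
GRADE_ORDER: tuple[str, ...] = ("R1", "R2", "R3", "R4", "M1", "M2", "BLIND")

#: Severity class of each grade: R1 mild; R2, M1 moderate; R3 severe;
#: R4, M2 sight-threatening; blindness its own class.
SEVERITY_CLASS: dict[str, str] = {
    "R1": "mild",
    "R2": "moderate",
    "M1": "moderate",
    "R3": "severe",
    "R4": "sight_threatening",
    "M2": "sight_threatening",
    "BLIND": "blind",
}

#: Default supportive-care eligibility: visual aids for mild/moderate/severe
#: (R1, R2, M1, R3); psychological support, home nursing and a government
#: pension for sight-threatening disease and blindness (R4, M2, BLIND).
DEFAULT_SUPPORTIVE_CARE: dict[str, dict[str, bool]] = {
    **{g: {"visual_aids": True, "psychological": False, "home_nurse": False, "pension": False}
       for g in ("R1", "R2", "M1", "R3")},
    **{g: {"visual_aids": False, "psychological": True, "home_nurse": True, "pension": True}
       for g in ("R4", "M2", "BLIND")},
}

Fraction = Annotated[float, Field(ge=0.0, le=1.0)]
NonNegative = Annotated[float, Field(ge=0.0)]
Positive = Annotated[float, Field(gt=0.0)]

CostCategory = Literal[
    "medication", "procedure", "monitoring", "visual_aid", "psychological", "nursing"
]

#: Well-known unit-cost identifiers consumed by the supportive-care rules.
VISUAL_AID_ITEM = "optical_devices"
PSYCHOLOGIST_ITEM = "psychologist_visit"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeverityGrade(_Strict):
    """A severity grade and its class; the mapping is fixed by convention."""

    code: GradeCode
    severity_class: SeverityClass

    @model_validator(mode="after")
    def _check_mapping(self) -> "SeverityGrade":
        expected = SEVERITY_CLASS[self.code]
        if self.severity_class != expected:
            raise ValueError(
                f"grade {self.code} must have severity_class {expected!r}, "
                f"got {self.severity_class!r}"
            )
        return self


class PopulationInputs(_Strict):
    """Population denominators and the prevalence cascade (Scottish grading).

    All prevalences are fractions of the diabetic population except
    ``diabetic_prevalence`` (fraction of the adult population).
    ``combined_prevalence`` is the prevalence of retinopathy and/or
    maculopathy and anchors the double-counting correction factor.
    """

    adult_population: NonNegative
    diabetic_prevalence: Fraction
    blindness_prevalence: Fraction
    retinopathy_prevalence: Fraction
    maculopathy_prevalence: Fraction
    combined_prevalence: Fraction
    grade_prevalence: Dict[Literal["R1", "R2", "R3", "R4", "M1", "M2"], Fraction]

    @field_validator("grade_prevalence")
    @classmethod
    def _fill_missing_grades(cls, v: dict) -> dict:
        return {g: float(v.get(g, 0.0)) for g in RM_GRADES}

    @model_validator(mode="after")
    def _check_overlap(self) -> "PopulationInputs":
        if self.combined_prevalence > self.retinopathy_prevalence + self.maculopathy_prevalence + 1e-12:
            raise ValueError(
                "combined_prevalence exceeds retinopathy_prevalence + "
                "maculopathy_prevalence: correction factor > 1"
            )
        return self


class UnitCost(_Strict):
    cost_sar: NonNegative
    category: CostCategory


class FrequencySpec(_Strict):
    """How often a resource is consumed; annualization is done by the
    direct-cost engine (weeks-based frequencies use a 52-week year)."""

    kind: Literal["per_year", "every_n_weeks", "every_n_months", "once_at_diagnosis"]
    n: Optional[Positive] = None
    count: Optional[NonNegative] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "FrequencySpec":
        if self.kind in ("every_n_weeks", "every_n_months") and self.n is None:
            raise ValueError(f"frequency kind {self.kind!r} requires n")
        if self.kind == "per_year" and self.count is None:
            raise ValueError("frequency kind 'per_year' requires count")
        return self


class ProtocolLine(_Strict):
    """One resource line of a treatment protocol or cost bundle.

    ``multiplicity`` is the explicit per-patient dose multiplier (e.g. eyes
    treated, hospitalization days per event); default one.
    """

    item: str
    frequency: FrequencySpec
    multiplicity: Positive = 1.0


class AdverseEventSpec(_Strict):
    """An adverse event costed in expectation: probability per treated
    patient-year times the annualized cost of its management bundle."""

    name: str
    probability: Fraction
    cost_bundle: List[ProtocolLine]


class SupportiveCareFlags(_Strict):
    visual_aids: bool = False
    psychological: bool = False
    home_nurse: bool = False
    pension: bool = False


class ProductivityAssumptions(_Strict):
    """Human-capital productivity inputs.

    Two wage tiers apply: severely impaired / sight-threatened / blind
    patients earn ``monthly_salary_sar`` (a published reduced wage), while
    mildly or moderately impaired patients and all caregivers are valued at
    the economy-wide ``gdp_daily_wage_sar`` (a GDP-derived estimate).
    """

    employment_rate: Fraction
    absenteeism_days: Dict[GradeCode, NonNegative]
    caregiver_days: Dict[GradeCode, NonNegative]
    monthly_salary_sar: NonNegative
    gdp_daily_wage_sar: NonNegative
    working_days_per_month: Positive
    working_days_per_week: Positive

    @field_validator("absenteeism_days", "caregiver_days")
    @classmethod
    def _fill_days(cls, v: dict) -> dict:
        return {g: float(v.get(g, 0.0)) for g in GRADE_ORDER}


class EconomyInputs(_Strict):
    ppp_rate_sar_per_intl_dollar: Positive
    gdp_sar: Positive
    pension_annual_sar: Positive
    nurse_annual_salary_sar: Positive


class ModelParameters(_Strict):
    """The complete declarative model specification."""

    coi_schema: Literal[1] = SCHEMA_VERSION
    population: PopulationInputs
    unit_costs: Dict[str, UnitCost]
    protocols: Dict[GradeCode, List[ProtocolLine]] = Field(default_factory=dict)
    adverse_events: Dict[GradeCode, List[AdverseEventSpec]] = Field(default_factory=dict)
    supportive_care: Dict[GradeCode, SupportiveCareFlags] = Field(default_factory=dict)
    productivity: ProductivityAssumptions
    economy: EconomyInputs
    #: Free-form notes carried through serialization, never used in computation.
    annotations: Dict[str, str] = Field(default_factory=dict)
    #: Parameter paths excluded from the one-way sensitivity analysis.
    owsa_exclude: List[str] = Field(default_factory=list)

    @field_validator("supportive_care")
    @classmethod
    def _fill_supportive(cls, v: dict) -> dict:
        out = {}
        for g in GRADE_ORDER:
            if g in v:
                out[g] = v[g]
            else:
                out[g] = SupportiveCareFlags(**DEFAULT_SUPPORTIVE_CARE.get(g, {}))
        return out

    @model_validator(mode="after")
    def _check_references(self) -> "ModelParameters":
        def _require(item: str, where: str) -> None:
            if item not in self.unit_costs:
                raise ValueError(f"unknown unit-cost item {item!r} referenced in {where}")

        for grade, lines in self.protocols.items():
            for line in lines:
                _require(line.item, f"protocols.{grade}")
        for grade, events in self.adverse_events.items():
            for ev in events:
                for line in ev.cost_bundle:
                    _require(line.item, f"adverse_events.{grade}.{ev.name}")
        for grade, flags in self.supportive_care.items():
            if flags.visual_aids:
                _require(VISUAL_AID_ITEM, f"supportive_care.{grade}.visual_aids")
            if flags.psychological:
                _require(PSYCHOLOGIST_ITEM, f"supportive_care.{grade}.psychological")
        return self


# ---------------------------------------------------------------------------
# Loading / saving / validation reports
# ---------------------------------------------------------------------------


class ConfigError(Exception):
    """Base class for parameter-file problems."""


class ConfigFormatError(ConfigError):
    """The file could not be parsed as YAML/JSON (message names the line)."""


class ConfigValidationError(ConfigError):
    """The file parsed but violates a schema invariant."""


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


@dataclass(frozen=True)
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _violations_from(exc: ValidationError) -> list[Violation]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        out.append(Violation(field=loc or "<root>", rule=err["msg"]))
    return out


def validate_parameters(params: ModelParameters | dict) -> ValidationReport:
    """Re-check every schema invariant; violations are returned as data.

    Accepts either a constructed :class:`ModelParameters` (useful after
    in-place mutation) or a raw mapping.
    """
    payload = params.model_dump() if isinstance(params, ModelParameters) else params
    try:
        ModelParameters.model_validate(payload)
    except ValidationError as exc:
        return ValidationReport(_violations_from(exc))
    return ValidationReport()


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a YAML or JSON parameter file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigFormatError(f"{path}: JSON parse error at line {exc.lineno}: {exc.msg}") from exc
    else:
        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigFormatError(f"{path}: YAML parse error{line}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigFormatError(f"{path}: top level must be a mapping")
    if payload.get("coi_schema") != SCHEMA_VERSION:
        raise ConfigValidationError(
            f"{path}: missing or unsupported schema version (need coi_schema: {SCHEMA_VERSION})"
        )
    try:
        return ModelParameters.model_validate(payload)
    except ValidationError as exc:
        msgs = "; ".join(str(v) for v in _violations_from(exc))
        raise ConfigValidationError(f"{path}: {msgs}") from exc


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize to YAML or JSON (by extension); round-trips value-identically."""
    path = Path(path)
    payload = params.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False, allow_unicode=True), encoding="utf-8")


def default_ksa_parameters() -> ModelParameters:
    """The bundled Saudi-Arabia 2024 parameterization."""
    ref = resources.files("visioncost.data").joinpath("ksa_2024.yaml")
    with resources.as_file(ref) as p:
        return load_parameters(p)


def ksa_2024_reported() -> dict:
    """Published 2024 KSA base-case component totals and SAR/I$ unit-cost
    pairs, used for aggregation-identity checks and PPP-rate derivation."""
    ref = resources.files("visioncost.data").joinpath("ksa_2024_reported.json")
    return json.loads(ref.read_text(encoding="utf-8"))
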