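"""Indirect costs: productivity losses (human capital) and pensions.

Lost production is valued by the human capital method — wage per day ×
lost working days × affected persons.  Three streams are computed per
grade:

* patient absenteeism, attenuated by the employment rate (only employed
  patients lose paid work);
* caregiver absenteeism, valued at the economy-wide wage with no
  employment attenuation (no caregiver employment rate is assumed);
* government disability pensions, a transfer paid per eligible person
  independent of wages.

Two wage tiers apply: severely impaired, sight-threatened and blind
patients earn the reduced published monthly salary, while mildly and
moderately impaired patients — and all caregivers — are valued at a
GDP-derived average daily wage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cascade import PopulationCascade
from .config import GRADE_ORDER, SEVERITY_CLASS, ModelParameters, ProductivityAssumptions

#: Severity classes valued at the GDP-derived wage (the rest use the
#: reduced monthly salary for severely impaired / blind individuals).
_GDP_WAGE_CLASSES = frozenset({"mild", "moderate"})

STREAMS: tuple[str, ...] = ("patient_productivity", "caregiver_productivity", "pension")


def daily_wage(monthly_salary: float, working_days_per_month: float) -> float:
    """Wage per working day from a monthly salary."""
    if working_days_per_month <= 0:
        raise ValueError("working_days_per_month must be positive")
    return monthly_salary / working_days_per_month


def wage_for_grade(grade: str, productivity: ProductivityAssumptions) -> float:
    """Daily wage applied to patients of a grade (two-tier rule)."""
    if SEVERITY_CLASS[grade] in _GDP_WAGE_CLASSES:
        return productivity.gdp_daily_wage_sar
    return daily_wage(productivity.monthly_salary_sar, productivity.working_days_per_month)


def patient_productivity_loss(
    grade_count: float, employment_rate: float, absent_days: float, wage: float
) -> float:
    """Annual patient productivity loss: count × employment × days × wage."""
    return grade_count * employment_rate * absent_days * wage


def caregiver_productivity_loss(
    grade_count: float, caregiver_days: float, wage: float
) -> float:
    """Annual caregiver productivity loss (no employment attenuation)."""
    return grade_count * caregiver_days * wage


def pension_cost(eligible_count: float, pension_annual: float) -> float:
    """Annual government pension transfer for an eligible population."""
    return eligible_count * pension_annual


@dataclass(frozen=True)
class IndirectBreakdown:
    """Indirect costs by stream, with the per-grade decomposition."""

    patient_productivity: float
    caregiver_productivity: float
    pension: float
    per_grade: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.patient_productivity + self.caregiver_productivity + self.pension

    @classmethod
    def from_totals(
        cls, patient: float, caregiver: float, pension: float
    ) -> "IndirectBreakdown":
        """Wrap externally supplied stream totals (e.g. published figures)."""
        return cls(
            patient_productivity=float(patient),
            caregiver_productivity=float(caregiver),
            pension=float(pension),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in GRADE_ORDER:
            streams = self.per_grade.get(g, {})
            rows.append({"grade": g, **{s: streams.get(s, 0.0) for s in STREAMS}})
        rows.append(
            {
                "grade": "TOTAL",
                "patient_productivity": self.patient_productivity,
                "caregiver_productivity": self.caregiver_productivity,
                "pension": self.pension,
            }
        )
        return pd.DataFrame(rows)


def indirect_costs(cascade: PopulationCascade, params: ModelParameters) -> IndirectBreakdown:
    """Aggregate annual indirect costs over the population cascade."""
    prod = params.productivity
    totals = {s: 0.0 for s in STREAMS}
    per_grade: dict[str, dict[str, float]] = {}

    for grade in GRADE_ORDER:
        count = cascade.grade_counts.get(grade, 0.0)
        patient = patient_productivity_loss(
            count,
            prod.employment_rate,
            prod.absenteeism_days.get(grade, 0.0),
            wage_for_grade(grade, prod),
        )
        caregiver = caregiver_productivity_loss(
            count, prod.caregiver_days.get(grade, 0.0), prod.gdp_daily_wage_sar
        )
        pension = (
            pension_cost(count, params.economy.pension_annual_sar)
            if params.supportive_care[grade].pension
            else 0.0
        )
        per_grade[grade] = {
            "patient_productivity": patient,
            "caregiver_productivity": caregiver,
            "pension": pension,
        }
        totals["patient_productivity"] += patient
        totals["caregiver_productivity"] += caregiver
        totals["pension"] += pension

    return IndirectBreakdown(
        patient_productivity=totals["patient_productivity"],
        caregiver_productivity=totals["caregiver_productivity"],
        pension=totals["pension"],
        per_grade=per_grade,
    )
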