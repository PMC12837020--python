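"""Direct medical costs: protocols, adverse events, supportive care.

Annual per-patient cost for a grade is the sum of three parts:

* treatment-protocol resources — each protocol line contributes
  annualized frequency × multiplicity × unit cost, booked to the
  ``medication`` or ``surgery_resources`` component by its unit-cost
  category;
* adverse events — costed in expectation (probability × management
  bundle cost), never simulated: the model is deterministic;
* supportive care — visual aids, psychological support (monthly
  psychologist visits), and an annual home-care nurse, switched per
  grade by eligibility flags.

Grade totals are per-patient cost × grade count, so every output is
linear in both the population cascade and the unit costs, and the same
money can be partitioned either by component or by grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .cascade import PopulationCascade
from .config import (
    GRADE_ORDER,
    PSYCHOLOGIST_ITEM,
    VISUAL_AID_ITEM,
    AdverseEventSpec,
    EconomyInputs,
    FrequencySpec,
    ModelParameters,
    ProtocolLine,
    SupportiveCareFlags,
    UnitCost,
)

#: Direct-cost components, mirroring the published breakdown.
COMPONENTS: tuple[str, ...] = (
    "medication",
    "surgery_resources",
    "adverse_events",
    "psychological",
    "visual_aids",
    "home_nurse",
)

#: Unit-cost category → direct-cost component for ordinary protocol lines.
CATEGORY_TO_COMPONENT: dict[str, str] = {
    "medication": "medication",
    "procedure": "surgery_resources",
    "monitoring": "surgery_resources",
    "visual_aid": "visual_aids",
    "psychological": "psychological",
    "nursing": "home_nurse",
}

#: Psychological support convention: one psychologist visit per month.
PSYCH_VISITS_PER_YEAR = 12


def annualize(freq: FrequencySpec) -> float:
    """Events per year implied by a frequency spec.

    every_n_weeks uses a 52-week year (every 4 weeks → 13/year, not 12);
    every_n_months uses 12/n; once_at_diagnosis counts once in the
    one-year horizon.
    """
    if freq.kind == "per_year":
        return float(freq.count)
    if freq.kind == "once_at_diagnosis":
        return 1.0
    if freq.n is None or freq.n <= 0:
        raise ValueError(f"frequency {freq.kind} requires n > 0")
    if freq.kind == "every_n_weeks":
        return 52.0 / freq.n
    return 12.0 / freq.n  # every_n_months


def protocol_cost_per_patient(
    lines: Iterable[ProtocolLine], costs: Mapping[str, UnitCost]
) -> dict[str, float]:
    """Annual per-patient protocol cost split by component."""
    out = {c: 0.0 for c in COMPONENTS}
    for line in lines:
        try:
            unit = costs[line.item]
        except KeyError:
            raise KeyError(f"unknown unit-cost item {line.item!r}") from None
        component = CATEGORY_TO_COMPONENT[unit.category]
        out[component] += annualize(line.frequency) * line.multiplicity * unit.cost_sar
    return out


def bundle_cost(lines: Iterable[ProtocolLine], costs: Mapping[str, UnitCost]) -> float:
    """Annualized total cost of a management bundle (category-blind)."""
    return sum(v for v in protocol_cost_per_patient(lines, costs).values())


def expected_adverse_event_cost(
    aes: Iterable[AdverseEventSpec], costs: Mapping[str, UnitCost]
) -> float:
    """Expected annual adverse-event cost per treated patient."""
    return sum(ev.probability * bundle_cost(ev.cost_bundle, costs) for ev in aes)


def supportive_care_cost(
    grade: str,
    flags: SupportiveCareFlags,
    costs: Mapping[str, UnitCost],
    economy: EconomyInputs,
) -> dict[str, float]:
    """Annual per-patient supportive-care cost split by component."""
    out = {c: 0.0 for c in COMPONENTS}
    if flags.visual_aids:
        out["visual_aids"] += costs[VISUAL_AID_ITEM].cost_sar
    if flags.psychological:
        out["psychological"] += PSYCH_VISITS_PER_YEAR * costs[PSYCHOLOGIST_ITEM].cost_sar
    if flags.home_nurse:
        out["home_nurse"] += economy.nurse_annual_salary_sar
    return out


@dataclass(frozen=True)
class ComponentBreakdown:
    """Direct costs partitioned two ways: by component and by grade.

    ``per_component`` sums to the same money as ``per_grade_total``
    (partition identity).  When built from published component totals the
    per-grade maps are empty.
    """

    per_component: Mapping[str, float]
    per_grade_per_patient: Mapping[str, float] = field(default_factory=dict)
    per_grade_total: Mapping[str, float] = field(default_factory=dict)
    per_grade_component: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.per_component.values())

    @classmethod
    def from_component_totals(cls, totals: Mapping[str, float]) -> "ComponentBreakdown":
        """Wrap externally supplied component totals (e.g. published
        figures) so they can enter the aggregation identities."""
        per = {c: float(totals.get(c, 0.0)) for c in COMPONENTS}
        unknown = set(totals) - set(COMPONENTS)
        if unknown:
            raise KeyError(f"unknown direct-cost components: {sorted(unknown)}")
        return cls(per_component=per)

    def to_frame(self) -> pd.DataFrame:
        """Grades × components table with a components-total row."""
        rows = []
        for g in GRADE_ORDER:
            comp = self.per_grade_component.get(g, {})
            rows.append({"grade": g, **{c: comp.get(c, 0.0) for c in COMPONENTS},
                         "total": self.per_grade_total.get(g, 0.0)})
        rows.append({"grade": "TOTAL", **{c: self.per_component.get(c, 0.0) for c in COMPONENTS},
                     "total": self.total})
        return pd.DataFrame(rows)


def direct_costs(cascade: PopulationCascade, params: ModelParameters) -> ComponentBreakdown:
    """Aggregate annual direct medical costs over the population cascade."""
    per_component = {c: 0.0 for c in COMPONENTS}
    per_grade_per_patient: dict[str, float] = {}
    per_grade_total: dict[str, float] = {}
    per_grade_component: dict[str, dict[str, float]] = {}

    for grade in GRADE_ORDER:
        count = cascade.grade_counts.get(grade, 0.0)
        comp = protocol_cost_per_patient(params.protocols.get(grade, []), params.unit_costs)
        comp["adverse_events"] += expected_adverse_event_cost(
            params.adverse_events.get(grade, []), params.unit_costs
        )
        care = supportive_care_cost(
            grade, params.supportive_care[grade], params.unit_costs, params.economy
        )
        for c in COMPONENTS:
            comp[c] += care[c]

        per_patient = sum(comp.values())
        per_grade_per_patient[grade] = per_patient
        per_grade_total[grade] = per_patient * count
        per_grade_component[grade] = {c: comp[c] * count for c in COMPONENTS}
        for c in COMPONENTS:
            per_component[c] += comp[c] * count

    return ComponentBreakdown(
        per_component=per_component,
        per_grade_per_patient=per_grade_per_patient,
        per_grade_total=per_grade_total,
        per_grade_component=per_grade_component,
    )
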