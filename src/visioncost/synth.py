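"""Synthetic scenarios and an independent costing oracle.

``generate_scenario`` draws random but structurally valid model
parameterizations — a prevalence cascade with a valid overlap
correction, per-grade protocols over a random unit-cost registry,
adverse-event expectations and productivity assumptions — so that every
pipeline stage can be exercised without external data.  Scenarios are
fully determined by their seed and make no attempt to match real-world
magnitudes; they exist for correctness testing, not realism.

``oracle_total`` recomputes the grand total by a deliberately naive
per-grade enumeration that shares no code with the cost engines; the
pipeline and the oracle must agree to floating-point accuracy on any
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    GRADE_ORDER,
    PSYCHOLOGIST_ITEM,
    RM_GRADES,
    VISUAL_AID_ITEM,
    ModelParameters,
)

_FREQ_KINDS = ("per_year", "every_n_weeks", "every_n_months", "once_at_diagnosis")


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape of a generated scenario; the seed fixes it completely."""

    seed: int
    n_grades: int = 6
    n_items: int = 12
    population_scale: float = 1_000_000.0
    cost_scale: float = 1_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_grades <= len(RM_GRADES):
            raise ValueError(f"n_grades must be in [0, {len(RM_GRADES)}]")
        if self.n_items < 0:
            raise ValueError("n_items must be >= 0")
        if self.population_scale <= 0 or self.cost_scale <= 0:
            raise ValueError("scales must be positive")


def _frequency(rng: np.random.Generator) -> dict:
    kind = _FREQ_KINDS[int(rng.integers(len(_FREQ_KINDS)))]
    if kind == "per_year":
        return {"kind": kind, "count": float(np.round(rng.uniform(0.0, 24.0), 3))}
    if kind == "every_n_weeks":
        return {"kind": kind, "n": float(rng.choice([1, 2, 4, 6, 8, 13]))}
    if kind == "every_n_months":
        return {"kind": kind, "n": float(rng.choice([1, 2, 3, 6, 12]))}
    return {"kind": kind}


def _line(rng: np.random.Generator, items: list[str]) -> dict:
    return {
        "item": items[int(rng.integers(len(items)))],
        "frequency": _frequency(rng),
        "multiplicity": float(rng.choice([1.0, 1.0, 2.0, 3.0])),
    }


def generate_scenario(spec: ScenarioSpec) -> ModelParameters:
    """A random, schema-valid :class:`ModelParameters` for ``spec``."""
    rng = np.random.default_rng(spec.seed)

    # Population: grade prevalences scaled so their sum stays below 1, and
    # the combined prevalence drawn inside [max(ret, mac), ret + mac] so
    # the correction factor is always valid.
    active = list(RM_GRADES[: spec.n_grades])
    raw = rng.uniform(0.2, 1.0, size=len(active)) if active else np.array([])
    budget = float(rng.uniform(0.1, 0.9))
    grade_prev = {
        g: float(np.round(budget * raw[i] / raw.sum(), 6)) for i, g in enumerate(active)
    }
    ret = float(np.round(rng.uniform(0.05, 0.45), 6))
    mac = float(np.round(rng.uniform(0.05, 0.45), 6))
    combined = float(np.round(rng.uniform(max(ret, mac), ret + mac), 6))
    population = {
        "adult_population": float(np.round(spec.population_scale * rng.uniform(0.5, 2.0), 2)),
        "diabetic_prevalence": float(np.round(rng.uniform(0.05, 0.5), 6)),
        "blindness_prevalence": float(np.round(rng.uniform(0.0, 0.1), 6)),
        "retinopathy_prevalence": ret,
        "maculopathy_prevalence": mac,
        "combined_prevalence": combined,
        "grade_prevalence": grade_prev,
    }

    # Unit costs: log-uniform around cost_scale, random categories, plus
    # the two well-known supportive-care items.
    categories = ("medication", "procedure", "monitoring")
    unit_costs = {
        f"item_{i:02d}": {
            "cost_sar": float(np.round(spec.cost_scale * np.exp(rng.normal(0.0, 1.0)), 2)),
            "category": categories[int(rng.integers(len(categories)))],
        }
        for i in range(spec.n_items)
    }
    unit_costs[VISUAL_AID_ITEM] = {
        "cost_sar": float(np.round(spec.cost_scale * rng.uniform(0.5, 5.0), 2)),
        "category": "visual_aid",
    }
    unit_costs[PSYCHOLOGIST_ITEM] = {
        "cost_sar": float(np.round(spec.cost_scale * rng.uniform(0.1, 1.0), 2)),
        "category": "psychological",
    }
    protocol_items = sorted(set(unit_costs) - {VISUAL_AID_ITEM, PSYCHOLOGIST_ITEM})

    protocols: dict[str, list] = {g: [] for g in GRADE_ORDER}
    adverse_events: dict[str, list] = {g: [] for g in GRADE_ORDER}
    if protocol_items:
        for g in active:
            protocols[g] = [
                _line(rng, protocol_items) for _ in range(int(rng.integers(1, 7)))
            ]
            adverse_events[g] = [
                {
                    "name": f"ae_{g}_{j}",
                    "probability": float(np.round(rng.uniform(0.0, 0.5), 6)),
                    "cost_bundle": [
                        _line(rng, protocol_items) for _ in range(int(rng.integers(1, 4)))
                    ],
                }
                for j in range(int(rng.integers(0, 3)))
            ]

    supportive_care = {
        g: {
            "visual_aids": bool(rng.integers(2)),
            "psychological": bool(rng.integers(2)),
            "home_nurse": bool(rng.integers(2)),
            "pension": bool(rng.integers(2)),
        }
        for g in GRADE_ORDER
    }

    productivity = {
        "employment_rate": float(np.round(rng.uniform(0.0, 1.0), 6)),
        "absenteeism_days": {
            g: float(np.round(rng.uniform(0.0, 300.0), 2)) for g in GRADE_ORDER
        },
        "caregiver_days": {
            g: float(np.round(rng.uniform(0.0, 100.0), 2)) for g in GRADE_ORDER
        },
        "monthly_salary_sar": float(np.round(rng.uniform(1_000.0, 10_000.0), 2)),
        "gdp_daily_wage_sar": float(np.round(rng.uniform(50.0, 1_000.0), 2)),
        "working_days_per_month": 22.0,
        "working_days_per_week": 5.0,
    }
    economy = {
        "ppp_rate_sar_per_intl_dollar": float(np.round(rng.uniform(1.0, 5.0), 4)),
        "gdp_sar": float(np.round(spec.population_scale * spec.cost_scale * rng.uniform(10.0, 100.0), 2)),
        "pension_annual_sar": float(np.round(rng.uniform(1_000.0, 60_000.0), 2)),
        "nurse_annual_salary_sar": float(np.round(rng.uniform(10_000.0, 60_000.0), 2)),
    }

    return ModelParameters.model_validate(
        {
            "coi_schema": 1,
            "population": population,
            "unit_costs": unit_costs,
            "protocols": protocols,
            "adverse_events": adverse_events,
            "supportive_care": supportive_care,
            "productivity": productivity,
            "economy": economy,
        }
    )


# ---------------------------------------------------------------------------
# Independent oracle — a naive enumeration sharing no code with the engines.
# ---------------------------------------------------------------------------

# Oracle's own severity-tier table for the two-tier wage rule.
_ORACLE_GDP_WAGE_GRADES = ("R1", "R2", "M1")
_ORACLE_PSYCH_VISITS = 12


def oracle_total(params: ModelParameters) -> float:
    """Grand total (SAR) by brute-force per-grade enumeration."""
    d = params.model_dump()

    def events_per_year(freq: dict) -> float:
        kind = freq["kind"]
        if kind == "per_year":
            return freq["count"]
        if kind == "every_n_weeks":
            return 52.0 / freq["n"]
        if kind == "every_n_months":
            return 12.0 / freq["n"]
        return 1.0  # once at diagnosis

    pop = d["population"]
    diabetics = pop["adult_population"] * pop["diabetic_prevalence"]
    retino = diabetics * pop["retinopathy_prevalence"]
    maculo = diabetics * pop["maculopathy_prevalence"]
    either = diabetics * pop["combined_prevalence"]
    overlap_factor = either / (retino + maculo) if (retino + maculo) > 0 else 1.0

    counts = {
        g: diabetics * pop["grade_prevalence"].get(g, 0.0) * overlap_factor
        for g in ("R1", "R2", "R3", "R4", "M1", "M2")
    }
    counts["BLIND"] = diabetics * pop["blindness_prevalence"]

    total = 0.0
    for grade, n_patients in counts.items():
        per_patient = 0.0
        for line in d["protocols"].get(grade, []):
            per_patient += (
                events_per_year(line["frequency"])
                * line["multiplicity"]
                * d["unit_costs"][line["item"]]["cost_sar"]
            )
        for event in d["adverse_events"].get(grade, []):
            bundle = 0.0
            for line in event["cost_bundle"]:
                bundle += (
                    events_per_year(line["frequency"])
                    * line["multiplicity"]
                    * d["unit_costs"][line["item"]]["cost_sar"]
                )
            per_patient += event["probability"] * bundle
        care = d["supportive_care"][grade]
        if care["visual_aids"]:
            per_patient += d["unit_costs"]["optical_devices"]["cost_sar"]
        if care["psychological"]:
            per_patient += _ORACLE_PSYCH_VISITS * d["unit_costs"]["psychologist_visit"]["cost_sar"]
        if care["home_nurse"]:
            per_patient += d["economy"]["nurse_annual_salary_sar"]

        prod = d["productivity"]
        if grade in _ORACLE_GDP_WAGE_GRADES:
            patient_wage = prod["gdp_daily_wage_sar"]
        else:
            patient_wage = prod["monthly_salary_sar"] / prod["working_days_per_month"]
        per_patient += (
            prod["employment_rate"]
            * prod["absenteeism_days"].get(grade, 0.0)
            * patient_wage
        )
        per_patient += prod["caregiver_days"].get(grade, 0.0) * prod["gdp_daily_wage_sar"]
        if care["pension"]:
            per_patient += d["economy"]["pension_annual_sar"]

        total += n_patients * per_patient
    return total
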