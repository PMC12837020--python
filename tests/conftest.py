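import pytest

import visioncost as vc


@pytest.fixture(scope="session")
def ksa() -> vc.ModelParameters:
    """The bundled Saudi-Arabia 2024 parameterization."""
    return vc.default_ksa_parameters()


@pytest.fixture(scope="session")
def reported() -> dict:
    """Published 2024 KSA base-case figures (component totals, cost pairs)."""
    return vc.ksa_2024_reported()


def make_toy_parameters(**overrides) -> vc.ModelParameters:
    """A minimal hand-checkable model: one grade (R1), one protocol item,
    no overlap (CF = 1), no supportive care, no indirect costs.

    Diabetics = 1000 × 0.5 = 500; R1 count = 0.5 × 500 × 1 = 250;
    direct cost = 250 × 1/year × SAR 10 = SAR 2,500.
    """
    payload = {
        "coi_schema": 1,
        "population": {
            "adult_population": 1000.0,
            "diabetic_prevalence": 0.5,
            "blindness_prevalence": 0.0,
            "retinopathy_prevalence": 0.2,
            "maculopathy_prevalence": 0.2,
            "combined_prevalence": 0.4,
            "grade_prevalence": {"R1": 0.5},
        },
        "unit_costs": {
            "widget": {"cost_sar": 10.0, "category": "medication"},
            "unused": {"cost_sar": 99.0, "category": "procedure"},
        },
        "protocols": {
            "R1": [{"item": "widget", "frequency": {"kind": "per_year", "count": 1.0}}]
        },
        "supportive_care": {
            g: {"visual_aids": False, "psychological": False, "home_nurse": False, "pension": False}
            for g in vc.GRADE_ORDER
        },
        "productivity": {
            "employment_rate": 0.0,
            "absenteeism_days": {},
            "caregiver_days": {},
            "monthly_salary_sar": 0.0,
            "gdp_daily_wage_sar": 0.0,
            "working_days_per_month": 22.0,
            "working_days_per_week": 5.0,
        },
        "economy": {
            "ppp_rate_sar_per_intl_dollar": 2.0,
            "gdp_sar": 1e6,
            "pension_annual_sar": 1.0,
            "nurse_annual_salary_sar": 1.0,
        },
    }
    payload.update(overrides)
    return vc.ModelParameters.model_validate(payload)


@pytest.fixture()
def toy() -> vc.ModelParameters:
    return make_toy_parameters()
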