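"""Direct-cost engine: annualization, protocols, adverse events, care."""

import pytest

import visioncost as vc
from visioncost.cascade import build_cascade
from visioncost.config import FrequencySpec, ProtocolLine, UnitCost
from visioncost.direct import (
    annualize,
    direct_costs,
    expected_adverse_event_cost,
    protocol_cost_per_patient,
    supportive_care_cost,
)


@pytest.mark.parametrize(
    "freq, expected",
    [
        (FrequencySpec(kind="every_n_weeks", n=4), 13.0),
        (FrequencySpec(kind="every_n_weeks", n=2), 26.0),
        (FrequencySpec(kind="every_n_months", n=6), 2.0),
        (FrequencySpec(kind="every_n_months", n=1), 12.0),
        (FrequencySpec(kind="once_at_diagnosis"), 1.0),
        (FrequencySpec(kind="per_year", count=7.5), 7.5),
    ],
)
def test_annualize(freq, expected):
    assert annualize(freq) == expected


def test_annualize_rejects_nonpositive_interval():
    bad = FrequencySpec.model_construct(kind="every_n_weeks", n=0.0, count=None)
    with pytest.raises(ValueError):
        annualize(bad)


REGISTRY = {
    "anti_vegf": UnitCost(cost_sar=2942.40, category="medication"),
    "oct": UnitCost(cost_sar=380.0, category="monitoring"),
    "phaco": UnitCost(cost_sar=4400.0, category="procedure"),
    "iol": UnitCost(cost_sar=2800.0, category="procedure"),
}


class TestProtocolCost:
    def test_anti_vegf_every_four_weeks(self):
        lines = [ProtocolLine(item="anti_vegf", frequency=FrequencySpec(kind="every_n_weeks", n=4))]
        out = protocol_cost_per_patient(lines, REGISTRY)
        assert out["medication"] == pytest.approx(38_251.20)
        assert out["surgery_resources"] == 0.0

    def test_empty_protocol_is_free(self):
        assert sum(protocol_cost_per_patient([], REGISTRY).values()) == 0.0

    def test_linearity_in_multiplicity(self):
        once = ProtocolLine(item="oct", frequency=FrequencySpec(kind="per_year", count=4))
        doubled = once.model_copy(update={"multiplicity": 2.0})
        two_lines = protocol_cost_per_patient([once, once], REGISTRY)
        one_doubled = protocol_cost_per_patient([doubled], REGISTRY)
        assert two_lines == one_doubled

    def test_categories_route_to_components(self):
        lines = [
            ProtocolLine(item="anti_vegf", frequency=FrequencySpec(kind="per_year", count=1)),
            ProtocolLine(item="phaco", frequency=FrequencySpec(kind="per_year", count=1)),
            ProtocolLine(item="oct", frequency=FrequencySpec(kind="per_year", count=1)),
        ]
        out = protocol_cost_per_patient(lines, REGISTRY)
        assert out["medication"] == pytest.approx(2942.40)
        assert out["surgery_resources"] == pytest.approx(4400.0 + 380.0)

    def test_unknown_item_raises_lookup_error(self):
        lines = [ProtocolLine(item="nope", frequency=FrequencySpec(kind="once_at_diagnosis"))]
        with pytest.raises(KeyError, match="nope"):
            protocol_cost_per_patient(lines, REGISTRY)


class TestExpectedAdverseEventCost:
    def _cataract(self, p):
        return vc.config.AdverseEventSpec(
            name="cataract",
            probability=p,
            cost_bundle=[
                ProtocolLine(item="phaco", frequency=FrequencySpec(kind="once_at_diagnosis")),
                ProtocolLine(item="iol", frequency=FrequencySpec(kind="once_at_diagnosis")),
            ],
        )

    def test_expected_value_costing(self):
        assert expected_adverse_event_cost([self._cataract(0.4804)], REGISTRY) == pytest.approx(
            3458.88
        )

    def test_zero_probability(self):
        assert expected_adverse_event_cost([self._cataract(0.0)], REGISTRY) == 0.0

    def test_certainty_limit_equals_bundle_cost(self):
        assert expected_adverse_event_cost([self._cataract(1.0)], REGISTRY) == pytest.approx(7200.0)


class TestSupportiveCare:
    def test_visual_aids_only(self, ksa):
        out = supportive_care_cost("R1", ksa.supportive_care["R1"], ksa.unit_costs, ksa.economy)
        assert out["visual_aids"] == 3000.0
        assert sum(out.values()) == 3000.0

    def test_sight_threatening_package(self, ksa):
        out = supportive_care_cost("M2", ksa.supportive_care["M2"], ksa.unit_costs, ksa.economy)
        assert out["home_nurse"] == 37_000.0
        assert out["psychological"] == pytest.approx(12 * 345.0)
        assert out["visual_aids"] == 0.0

    def test_all_flags_false(self, ksa):
        flags = vc.SupportiveCareFlags()
        out = supportive_care_cost("R1", flags, ksa.unit_costs, ksa.economy)
        assert sum(out.values()) == 0.0


class TestDirectCosts:
    def test_partition_identity(self, ksa):
        breakdown = direct_costs(build_cascade(ksa.population), ksa)
        assert sum(breakdown.per_component.values()) == pytest.approx(
            sum(breakdown.per_grade_total.values()), rel=1e-6
        )

    def test_linearity_in_population(self, ksa):
        cascade = build_cascade(ksa.population)
        base = direct_costs(cascade, ksa)
        doubled = direct_costs(cascade.scaled(2.0), ksa)
        for c in vc.COMPONENTS:
            assert doubled.per_component[c] == pytest.approx(2 * base.per_component[c], rel=1e-12)

    def test_linearity_in_unit_costs(self, ksa):
        cascade = build_cascade(ksa.population)
        base = direct_costs(cascade, ksa)
        payload = ksa.model_dump()
        for item in payload["unit_costs"].values():
            item["cost_sar"] *= 3.0
        scaled_params = vc.ModelParameters.model_validate(payload)
        scaled = direct_costs(cascade, scaled_params)
        # nurse salary is an economy scalar, not a unit cost
        for c in vc.COMPONENTS:
            if c == "home_nurse":
                assert scaled.per_component[c] == pytest.approx(base.per_component[c], rel=1e-12)
            else:
                assert scaled.per_component[c] == pytest.approx(3 * base.per_component[c], rel=1e-9)

    def test_zero_unit_costs_zero_breakdown(self, ksa):
        payload = ksa.model_dump()
        for item in payload["unit_costs"].values():
            item["cost_sar"] = 0.0
        payload["economy"]["nurse_annual_salary_sar"] = 1e-9
        params = vc.ModelParameters.model_validate(payload)
        breakdown = direct_costs(build_cascade(params.population), params)
        assert breakdown.total == pytest.approx(0.0, abs=1.0)

    def test_toy_model_hand_enumeration(self, toy):
        breakdown = direct_costs(build_cascade(toy.population), toy)
        assert breakdown.total == pytest.approx(2500.0)
        assert breakdown.per_grade_per_patient["R1"] == pytest.approx(10.0)

    def test_export_frame_layout(self, ksa):
        frame = direct_costs(build_cascade(ksa.population), ksa).to_frame()
        assert list(frame["grade"])[-1] == "TOTAL"
        assert set(vc.COMPONENTS) <= set(frame.columns)
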