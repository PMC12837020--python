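"""Population cascade: prevalence scaling and overlap correction."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import visioncost as vc
from visioncost.cascade import build_cascade, correction_factor, scale_population

# Published derived counts (fractional persons, printed to 2 dp).
PUBLISHED_COUNTS = {
    "diabetic": 2_271_011.24,
    "blind": 74_943.37,
    "retinopathy": 783_498.88,
    "maculopathy": 461_015.28,
    "combined": 835_732.14,
}
PUBLISHED_GRADE_COUNTS = {
    "R1": 337_037.96,
    "R2": 76_252.93,
    "R3": 59_477.29,
    "R4": 53_377.05,
    "M1": 67_102.58,
    "M2": 242_484.32,
}


class TestScalePopulation:
    @pytest.mark.parametrize(
        "base, prevalence, expected",
        [
            (12_830_572, 0.177, 2_271_011.24),
            (2_271_011.24, 0.033, 74_943.37),
            (123_456.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, base, prevalence, expected):
        assert scale_population(base, prevalence) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("prevalence", [-0.1, 1.1])
    def test_out_of_range_prevalence(self, prevalence):
        with pytest.raises(ValueError):
            scale_population(100.0, prevalence)


class TestCorrectionFactor:
    def test_published_counts(self):
        cf = correction_factor(783_498.88, 461_015.28, 835_732.14)
        assert cf == pytest.approx(0.671533, abs=1e-6)

    def test_no_overlap_identity(self):
        assert correction_factor(1000.0, 0.0, 1000.0) == 1.0

    def test_complete_overlap_of_equal_sets(self):
        assert correction_factor(500.0, 500.0, 500.0) == 0.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            correction_factor(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            correction_factor(100.0, 100.0, 300.0)


class TestBuildCascade:
    def test_reconstructs_all_published_counts(self, ksa):
        c = build_cascade(ksa.population)
        assert c.diabetic_count == pytest.approx(PUBLISHED_COUNTS["diabetic"], abs=1)
        assert c.blind_count == pytest.approx(PUBLISHED_COUNTS["blind"], abs=1)
        assert c.retinopathy_count == pytest.approx(PUBLISHED_COUNTS["retinopathy"], abs=1)
        assert c.maculopathy_count == pytest.approx(PUBLISHED_COUNTS["maculopathy"], abs=1)
        assert c.combined_count == pytest.approx(PUBLISHED_COUNTS["combined"], abs=1)
        for grade, expected in PUBLISHED_GRADE_COUNTS.items():
            assert c.grade_counts[grade] == pytest.approx(expected, abs=1), grade

    def test_blind_count_not_overlap_corrected(self, ksa):
        c = build_cascade(ksa.population)
        assert c.grade_counts["BLIND"] == pytest.approx(c.diabetic_count * 0.033, rel=1e-12)

    def test_zero_grade_prevalences_still_valid(self, ksa):
        pop = ksa.population.model_copy(update={"grade_prevalence": {}})
        c = build_cascade(vc.PopulationInputs.model_validate(pop.model_dump()))
        assert all(c.grade_counts[g] == 0.0 for g in vc.RM_GRADES)
        assert 0 < c.correction_factor <= 1

    def test_fully_empty_disease_population(self, ksa):
        pop = vc.PopulationInputs(
            adult_population=1000.0,
            diabetic_prevalence=0.1,
            blindness_prevalence=0.0,
            retinopathy_prevalence=0.0,
            maculopathy_prevalence=0.0,
            combined_prevalence=0.0,
            grade_prevalence={},
        )
        c = build_cascade(pop)
        assert c.correction_factor == 1.0
        assert sum(c.grade_counts.values()) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_homogeneity_in_adult_population(self, ksa, k):
        base = build_cascade(ksa.population)
        scaled_pop = ksa.population.model_copy(
            update={"adult_population": ksa.population.adult_population * k}
        )
        scaled = build_cascade(scaled_pop)
        assert scaled.correction_factor == pytest.approx(base.correction_factor, rel=1e-12)
        for g in vc.GRADE_ORDER:
            assert scaled.grade_counts[g] == pytest.approx(base.grade_counts[g] * k, rel=1e-9)

    def test_monotonic_in_grade_prevalence(self, ksa):
        base = build_cascade(ksa.population)
        bumped_prev = dict(ksa.population.grade_prevalence)
        bumped_prev["R3"] *= 1.5
        bumped = build_cascade(ksa.population.model_copy(update={"grade_prevalence": bumped_prev}))
        assert bumped.grade_counts["R3"] > base.grade_counts["R3"]

    def test_scaled_helper_matches_rebuild(self, ksa):
        c = build_cascade(ksa.population).scaled(2.0)
        assert c.diabetic_count == pytest.approx(2 * PUBLISHED_COUNTS["diabetic"], abs=2)

    def test_export_frame(self, ksa):
        frame = build_cascade(ksa.population).to_frame()
        assert list(frame.columns) == ["grade", "count"]
        assert len(frame) == len(vc.GRADE_ORDER)


def test_cascade_is_immutable(ksa):
    c = build_cascade(ksa.population)
    with pytest.raises(dataclasses.FrozenInstanceError):
        c.diabetic_count = 0.0
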