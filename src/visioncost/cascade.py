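"""Population cascade: prevalence application and overlap correction.

Patient counts flow down a prevalence cascade — adults, diabetics, then
disease groups and severity grades as fractions of the diabetic
population.  Because retinopathy and maculopathy co-occur, summing the
per-grade prevalences would double-count patients with both; a
correction factor

    CF = (any retinopathy and/or maculopathy) / (any retinopathy + any maculopathy)

rescales every retinopathy/maculopathy grade so that the corrected grade
counts sum to the combined (either-condition) population.  The blindness
count is not corrected.  Counts stay fractional throughout: the model is
an expected-value accounting exercise, not a census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .config import GRADE_ORDER, RM_GRADES, PopulationInputs


@dataclass(frozen=True)
class PopulationCascade:
    """Per-grade patient counts after prevalence application and overlap
    correction.  ``grade_counts`` covers the six R/M grades plus BLIND."""

    diabetic_count: float
    blind_count: float
    retinopathy_count: float
    maculopathy_count: float
    combined_count: float
    correction_factor: float
    grade_counts: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Cascade as a tidy table (grade, count)."""
        rows = [{"grade": g, "count": self.grade_counts[g]} for g in GRADE_ORDER]
        return pd.DataFrame(rows)

    def scaled(self, k: float) -> "PopulationCascade":
        """The cascade for a population k times larger (CF unchanged)."""
        return PopulationCascade(
            diabetic_count=self.diabetic_count * k,
            blind_count=self.blind_count * k,
            retinopathy_count=self.retinopathy_count * k,
            maculopathy_count=self.maculopathy_count * k,
            combined_count=self.combined_count * k,
            correction_factor=self.correction_factor,
            grade_counts={g: c * k for g, c in self.grade_counts.items()},
        )


def scale_population(base: float, prevalence: float) -> float:
    """base × prevalence, continuous (no integer truncation)."""
    if base < 0:
        raise ValueError(f"base population must be >= 0, got {base}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    return base * prevalence


def correction_factor(retinopathy: float, maculopathy: float, combined: float) -> float:
    """Overlap correction factor combined / (retinopathy + maculopathy).

    Lies in (0, 1]: it equals 1 when the two conditions never co-occur
    (combined = sum) and 0.5 when two equal sets overlap completely.
    """
    denom = retinopathy + maculopathy
    if denom <= 0:
        raise ValueError("retinopathy + maculopathy must be positive")
    if not 0.0 <= combined <= denom + 1e-9 * denom:
        raise ValueError(
            f"combined count {combined} outside [0, retinopathy + maculopathy = {denom}]"
        )
    return combined / denom


def build_cascade(pop: PopulationInputs) -> PopulationCascade:
    """Derive all model population counts from :class:`PopulationInputs`.

    Grade counts for R1..M2 are grade prevalence × diabetic count × CF;
    the BLIND count is blindness prevalence × diabetic count, uncorrected.
    A fully empty disease population (retinopathy = maculopathy =
    combined = 0) is treated as the degenerate no-overlap case CF = 1.
    """
    diabetic = scale_population(pop.adult_population, pop.diabetic_prevalence)
    blind = scale_population(diabetic, pop.blindness_prevalence)
    retino = scale_population(diabetic, pop.retinopathy_prevalence)
    maculo = scale_population(diabetic, pop.maculopathy_prevalence)
    combined = scale_population(diabetic, pop.combined_prevalence)

    if retino + maculo > 0:
        cf = correction_factor(retino, maculo, combined)
    else:
        cf = 1.0  # no disease population: nothing to de-overlap

    grade_counts: dict[str, float] = {
        g: scale_population(diabetic, pop.grade_prevalence.get(g, 0.0)) * cf
        for g in RM_GRADES
    }
    grade_counts["BLIND"] = blind

    return PopulationCascade(
        diabetic_count=diabetic,
        blind_count=blind,
        retinopathy_count=retino,
        maculopathy_count=maculo,
        combined_count=combined,
        correction_factor=cf,
        grade_counts=grade_counts,
    )
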