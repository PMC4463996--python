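"""Schofield BMR, the EI/BMR plausibility ratio, and pre-scoring exclusions.

Implausible reporters are removed with a fixed-cut Goldberg-type screen:
reported energy intake divided by predicted basal metabolic rate below 0.5
(under-reporting) or above 2.0 (over-reporting) excludes the record, with
strict inequalities — a ratio of exactly 0.5 or 2.0 is retained. BMR comes
from the weight-only Schofield equations (MJ/day) with half-open age bands.
Incomplete records are excluded first, before the energy screen.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .model import EnergyFactors, FoodCompositionEntry, IntakeRecord
from .scoring import summarize_intake

__all__ = [
    "SCHOFIELD_COEFFICIENTS",
    "ScreeningStatus",
    "ScreeningResult",
    "schofield_bmr",
    "classify_reporter",
    "apply_exclusions",
    "screening_frame",
]

#: (sex, age_lo, age_hi) → (slope MJ/day per kg, intercept MJ/day); bands are
#: half-open [lo, hi), so age 30 falls in the 30–59 band.
SCHOFIELD_COEFFICIENTS: dict[tuple[str, int, int], tuple[float, float]] = {
    ("male", 18, 30): (0.063, 2.896),
    ("male", 30, 60): (0.048, 3.653),
    ("female", 18, 30): (0.062, 2.036),
    ("female", 30, 60): (0.034, 3.538),
}

EI_BMR_LOWER = 0.5
EI_BMR_UPPER = 2.0


class ScreeningStatus(str, Enum):
    included = "included"
    excluded_incomplete = "excluded_incomplete"
    excluded_under = "excluded_under"
    excluded_over = "excluded_over"


class ScreeningResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    bmr_mj_day: float
    energy_kj_day: float
    energy_kcal_day: float
    ei_bmr: float
    status: ScreeningStatus
    reason: str


def schofield_bmr(
    sex: str,
    age: int,
    weight_kg: float,
    coefficients: Mapping[tuple[str, int, int], tuple[float, float]] | None = None,
) -> float:
    """Predicted basal metabolic rate in MJ/day from the weight-only equations."""
    if weight_kg <= 0:
        raise ValueError(f"non-positive weight: {weight_kg}")
    coefficients = coefficients or SCHOFIELD_COEFFICIENTS
    for (s, lo, hi), (slope, intercept) in coefficients.items():
        if s == sex and lo <= age < hi:
            return slope * weight_kg + intercept
    raise ValueError(f"no Schofield band covers sex={sex}, age={age}")


def classify_reporter(
    energy_kcal_day: float,
    bmr_mj_day: float,
    factors: EnergyFactors | None = None,
) -> tuple[float, ScreeningStatus]:
    """EI/BMR ratio and its status under the fixed 0.5/2.0 cuts (strict)."""
    if bmr_mj_day <= 0:
        raise ValueError(f"non-positive BMR: {bmr_mj_day}")
    if energy_kcal_day < 0:
        raise ValueError(f"negative energy intake: {energy_kcal_day}")
    factors = factors or EnergyFactors()
    energy_mj = energy_kcal_day * factors.kj_per_kcal / 1000.0
    ratio = energy_mj / bmr_mj_day
    if ratio < EI_BMR_LOWER:
        return ratio, ScreeningStatus.excluded_under
    if ratio > EI_BMR_UPPER:
        return ratio, ScreeningStatus.excluded_over
    return ratio, ScreeningStatus.included


def _screen_one(
    record: IntakeRecord,
    composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry],
    factors: EnergyFactors,
) -> ScreeningResult:
    p = record.profile
    bmr = schofield_bmr(p.sex, p.age, p.weight_kg)
    summary = summarize_intake(record, composition, factors)
    if not record.complete:
        status, reason = ScreeningStatus.excluded_incomplete, "incomplete baseline response"
        ratio = summary.energy_kj_day / 1000.0 / bmr
    else:
        ratio, status = classify_reporter(summary.energy_kcal_day, bmr, factors)
        reason = {
            ScreeningStatus.included: "EI/BMR within [0.5, 2.0]",
            ScreeningStatus.excluded_under: "EI/BMR < 0.5 (under-reporter)",
            ScreeningStatus.excluded_over: "EI/BMR > 2.0 (over-reporter)",
        }[status]
    return ScreeningResult(
        participant_id=p.participant_id,
        bmr_mj_day=bmr,
        energy_kj_day=summary.energy_kj_day,
        energy_kcal_day=summary.energy_kcal_day,
        ei_bmr=ratio,
        status=status,
        reason=reason,
    )


def apply_exclusions(
    cohort: Sequence[IntakeRecord],
    composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry],
    factors: EnergyFactors | None = None,
) -> tuple[list[IntakeRecord], list[ScreeningResult]]:
    """Partition a cohort into the included set and a per-record exclusion log.

    Precedence: incompleteness first, then the EI/BMR screen. The log holds
    one row per input record; included + excluded counts always partition
    the input.
    """
    factors = factors or EnergyFactors()
    included: list[IntakeRecord] = []
    log: list[ScreeningResult] = []
    for record in cohort:
        result = _screen_one(record, composition, factors)
        log.append(result)
        if result.status is ScreeningStatus.included:
            included.append(record)
    return included, log


def screening_frame(log: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Exclusion log as a DataFrame (one row per screened participant)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "bmr_mj_day": r.bmr_mj_day,
                "energy_kj_day": r.energy_kj_day,
                "energy_kcal_day": r.energy_kcal_day,
                "ei_bmr": r.ei_bmr,
                "status": r.status.value,
                "reason": r.reason,
            }
            for r in log
        ]
    )
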