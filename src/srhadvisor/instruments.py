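"""Questionnaire-instrument scoring and derived categorical variables.

Covers the HSCL-10 mental-distress index, the Health Impact Index (HII)
comorbidity score, BMI categorisation, the 4-level self-rated-health (SRH)
encoding, and the count of unhealthy modifiable factors (UMF).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .profiles import UserProfile

__all__ = [
    "InstrumentError",
    "score_hscl10",
    "compute_hii",
    "bmi_category",
    "encode_srh",
    "count_umf",
    "DEFAULT_HII_WEIGHTS",
    "validate_hii_weights",
    "HSCL_DISTRESS_THRESHOLD",
    "HII_SCALE_MAX",
    "BMI_CUTPOINTS",
]


class InstrumentError(ValueError):
    """Raised on invalid instrument input."""


#: HSCL-10 index at or above this value indicates mental distress.
HSCL_DISTRESS_THRESHOLD = 1.85

#: The HII scale maximum (all conditions present).
HII_SCALE_MAX = 22

#: BMI category cutpoints in kg/m^2; intervals are half-open, lower-inclusive.
BMI_CUTPOINTS = (18.5, 25.0, 30.0)

# Condition weights for the 11-condition Health Impact Index.  The first four
# weights are the published ones; the remaining seven conditions carry
# placeholder weights chosen to complete the 0-22 scale and are expected to be
# overridden from a user-supplied table when the full published index is used.
DEFAULT_HII_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 2,
    "cerebrovascular_stroke": 2,
    "asthma": 2,
    "migraine": 1,
    # placeholder weights (configurable):
    "diabetes": 3,
    "cancer": 3,
    "chronic_bronchitis_emphysema": 2,
    "kidney_disease": 2,
    "osteoporosis": 2,
    "rheumatoid_arthritis": 2,
    "epilepsy": 1,
}


def validate_hii_weights(weights: Mapping[str, int], scale_max: int = HII_SCALE_MAX) -> None:
    """Check that a weight table is non-negative and sums to the scale maximum."""
    for name, w in weights.items():
        if not (isinstance(w, int) and w >= 0):
            raise InstrumentError(f"weight for {name!r} must be a non-negative integer, got {w!r}")
    total = sum(weights.values())
    if total != scale_max:
        raise InstrumentError(f"weights sum to {total}, expected the scale maximum {scale_max}")


def score_hscl10(items: Sequence[Optional[int]]) -> Optional[float]:
    """Score the 10-item Hopkins Symptom Checklist.

    Each item is an integer 1 ("no complaint") to 4 ("very much") or ``None``
    when unanswered.  The score is the mean over answered items; with fewer
    than seven answers the score is missing (``None``).

    Returns
    -------
    float in [1, 4], or None when fewer than 7 items were answered.
    """
    items = list(items)
    if len(items) != 10:
        raise InstrumentError(f"HSCL-10 requires exactly 10 items, got {len(items)}")
    answered = []
    for i, v in enumerate(items, start=1):
        if v is None:
            continue
        if not (isinstance(v, (int,)) and 1 <= v <= 4):
            raise InstrumentError(f"HSCL-10 item {i} must be in 1..4 or missing, got {v!r}")
        answered.append(v)
    if len(answered) < 7:
        return None
    return sum(answered) / len(answered)


def compute_hii(
    flags: Mapping[str, bool],
    weights: Mapping[str, int] = DEFAULT_HII_WEIGHTS,
) -> int:
    """Weighted comorbidity sum over flagged conditions.

    Parameters
    ----------
    flags : mapping condition name -> bool
        Presence or history of each condition.  Names must exist in the
        active weight table; unknown names are refused rather than guessed.
    weights : mapping condition name -> non-negative int
    """
    unknown = sorted(set(flags) - set(weights))
    if unknown:
        raise InstrumentError(f"conditions without weights: {unknown}")
    return sum(int(weights[name]) for name, present in flags.items() if present)


def bmi_category(bmi: float) -> str:
    """Categorise BMI (kg/m^2) using cutpoints 18.5, 25 and 30.

    Intervals are half-open and lower-inclusive, so 18.5 is "normal",
    25.0 is "overweight" and 30.0 is "obese".
    """
    if not bmi > 0:
        raise InstrumentError(f"BMI must be positive, got {bmi}")
    lo, mid, hi = BMI_CUTPOINTS
    if bmi < lo:
        return "underweight"
    if bmi < mid:
        return "normal"
    if bmi < hi:
        return "overweight"
    return "obese"


def encode_srh(raw: int) -> int:
    """Map the raw 5-level SRH answer to the 4-level analysis scale.

    Raw levels are 1 "very poor" .. 5 "excellent"; "very poor" is merged into
    "poor", giving 1 poor, 2 not so good, 3 good, 4 excellent.
    """
    if not (isinstance(raw, int) and 1 <= raw <= 5):
        raise InstrumentError(f"raw SRH must be an integer in 1..5, got {raw!r}")
    return max(raw - 1, 1)


def count_umf(profile: UserProfile) -> int:
    """Count the five unhealthy modifiable factors present in a profile.

    The factors are: exercising less than once a week, HbA1c >= 6.5 %,
    overweight or obesity, current smoking, and mental distress
    (HSCL-10 >= 1.85).
    """
    for field in ("pa_frequency", "hba1c_high", "bmi_category", "smoker", "hscl"):
        if getattr(profile, field, None) is None:
            raise InstrumentError(f"cannot resolve UMF factor from missing field {field!r}")
    return sum(
        [
            profile.pa_frequency == "lt1_per_week",
            bool(profile.hba1c_high),
            profile.bmi_category in ("overweight", "obese"),
            bool(profile.smoker),
            profile.hscl >= HSCL_DISTRESS_THRESHOLD,
        ]
    )
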