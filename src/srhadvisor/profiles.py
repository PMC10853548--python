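"""Domain types for a single person's covariate state.

The unit the self-rated-health (SRH) model predicts on is a
:class:`UserProfile`: one person's age, socioeconomic context, comorbidity
burden, mental-distress index and modifiable lifestyle state.  All categorical
fields use fixed vocabularies matching the survey instruments; the profile is
immutable and validated on construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

__all__ = [
    "ProfileError",
    "UserProfile",
    "SEXES",
    "EDUCATION_LEVELS",
    "BMI_CATEGORIES",
    "PA_FREQUENCIES",
    "PA_INTENSITIES",
    "SRH_LABELS",
]


class ProfileError(ValueError):
    """Raised when a profile field violates its invariant."""


SEXES = ("female", "male")
EDUCATION_LEVELS = ("primary", "upper_secondary", "university")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
#: Physical-activity frequency; the survey's "never" answer is merged into
#: "less than once a week".
PA_FREQUENCIES = ("lt1_per_week", "1_per_week", "2_3_per_week", "ge4_per_week")
PA_INTENSITIES = ("mild", "moderate", "hard")
#: 4-level SRH after merging "very poor" into "poor".
SRH_LABELS = {1: "poor", 2: "not so good", 3: "good", 4: "excellent"}


def _check_choice(name: str, value: Any, choices: tuple[str, ...]) -> None:
    if value not in choices:
        raise ProfileError(f"{name}={value!r} not one of {choices}")


@dataclass(frozen=True)
class UserProfile:
    """One person's covariate state.

    Parameters
    ----------
    age : float
        Age in years, must be positive.
    sex : {"female", "male"}
    education : {"primary", "upper_secondary", "university"}
        Highest attained education level ("primary" covers primary and
        partly-secondary schooling).
    lives_with_spouse : bool
    friend_support : bool
        Whether the person reports sufficient support from friends.
    hii : float
        Health impact index (weighted comorbidity sum), 0-22.
    hscl : float
        HSCL-10 mental-distress index, mean of item scores, in [1, 4].
    bmi_category : {"underweight", "normal", "overweight", "obese"}
    pa_frequency : {"lt1_per_week", "1_per_week", "2_3_per_week", "ge4_per_week"}
    pa_intensity : {"mild", "moderate", "hard"}
    smoker : bool
        Currently smokes.
    hba1c_high : bool
        Glycated haemoglobin HbA1c >= 6.5 % (diabetic range).
    """

    age: float
    sex: str
    education: str
    lives_with_spouse: bool
    friend_support: bool
    hii: float
    hscl: float
    bmi_category: str
    pa_frequency: str
    pa_intensity: str
    smoker: bool
    hba1c_high: bool

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ProfileError(f"age must be positive, got {self.age}")
        _check_choice("sex", self.sex, SEXES)
        _check_choice("education", self.education, EDUCATION_LEVELS)
        _check_choice("bmi_category", self.bmi_category, BMI_CATEGORIES)
        _check_choice("pa_frequency", self.pa_frequency, PA_FREQUENCIES)
        _check_choice("pa_intensity", self.pa_intensity, PA_INTENSITIES)
        if not 0 <= float(self.hii) <= 22:
            raise ProfileError(f"hii must be in [0, 22], got {self.hii}")
        if not 1 <= float(self.hscl) <= 4:
            raise ProfileError(f"hscl must be in [1, 4], got {self.hscl}")
        for name in ("lives_with_spouse", "friend_support", "smoker", "hba1c_high"):
            value = getattr(self, name)
            if not isinstance(value, (bool,)):
                raise ProfileError(f"{name} must be a bool, got {value!r}")

    def replace(self, **changes: Any) -> "UserProfile":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
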