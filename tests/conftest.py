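import numpy as np
import pytest

from srhadvisor import default_coefficients, REFERENCE_PROFILE
from srhadvisor.profiles import (
    UserProfile,
    SEXES,
    EDUCATION_LEVELS,
    BMI_CATEGORIES,
    PA_FREQUENCIES,
    PA_INTENSITIES,
)
from srhadvisor.synth import default_spec, generate_cohort


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture
def reference():
    return REFERENCE_PROFILE


def random_profile(rng: np.random.Generator) -> UserProfile:
    """A uniformly scrambled but valid profile."""
    return UserProfile(
        age=float(rng.uniform(30, 90)),
        sex=str(rng.choice(SEXES)),
        education=str(rng.choice(EDUCATION_LEVELS)),
        lives_with_spouse=bool(rng.random() < 0.5),
        friend_support=bool(rng.random() < 0.5),
        hii=float(rng.integers(0, 10)),
        hscl=float(rng.uniform(1, 4)),
        bmi_category=str(rng.choice(BMI_CATEGORIES[1:])),  # skip underweight: no coefficient
        pa_frequency=str(rng.choice(PA_FREQUENCIES)),
        pa_intensity=str(rng.choice(PA_INTENSITIES)),
        smoker=bool(rng.random() < 0.5),
        hba1c_high=bool(rng.random() < 0.5),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort big enough for a full-model fit (seconds)."""
    return generate_cohort(default_spec(n_participants=2000), seed=42)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    from srhadvisor.fitting import fit_mixed_model

    return fit_mixed_model(small_cohort)
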