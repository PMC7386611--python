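import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import labelsim as ls

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def targets():
    return ls.CalibrationTargets()


@pytest.fixture(scope="session")
def cohort_small():
    """Calibrated 600-person cohort after exclusions (fixed seed)."""
    cohort = ls.generate_cohort(600, seed=7)
    cohort, _ = ls.apply_exclusions(cohort)
    return cohort


@pytest.fixture(scope="session")
def params():
    return ls.HallParameters()


@pytest.fixture(scope="session")
def state_small(cohort_small, params):
    return ls.init_state(cohort_small, params)


@pytest.fixture(scope="session")
def reference_adult():
    """One adult at the survey-mean anthropometry (72.38 kg, BMI 28.34)."""
    height = float(np.sqrt(72.38 / 28.34))
    return pd.DataFrame(
        {
            "person_id": [0],
            "age": [40],
            "sex": ["female"],
            "ses": ["middle"],
            "height": [height],
            "weight": [72.38],
            "bmi": [28.34],
            "beverage_kcal": [220.9],
            "snack_kcal": [453.1],
            "total_energy_kcal": [2200.0],
            "beverage_sodium_mg": [44.2],
            "snack_sodium_mg": [679.7],
            "beverage_servings": [1.47],
            "survey_weight": [1.0],
            "stratum_id": [0],
            "psu_id": [0],
        }
    )


def weighted_mean(cohort, values):
    return float(np.average(values, weights=cohort["survey_weight"]))
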