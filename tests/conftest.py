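import numpy as np
import pytest

from alivalid.ali_core import load_component_specs
from alivalid.synthetic_cohort import GeneratorConfig, generate_cohort

#: Generating coefficients used across simulation tests: baseline odds 0.23,
#: odds ratio 1.12 per 0.1 index points, odds ratio 1.11 per decade of age.
BETA_TRUE = (float(np.log(0.23)), float(np.log(1.12) / 0.1),
             float(np.log(1.11)))

ANCHORED = ["systolic_bp", "diastolic_bp", "bmi", "triglycerides",
            "total_cholesterol", "crp", "hba1c", "creatinine_clearance",
            "homocysteine"]


def low_error_config(seed: int = 0, n: int = 1000,
                     recovery: float = 0.9) -> GeneratorConfig:
    """Scenario with near-perfect non-missing data quality (tpr 1, fpr 0.01)
    and missingness confined to unhealthy values of anchored components, so
    that full recovery reconstructs the true index."""
    miss = {name: 0.25 for name in ANCHORED}
    miss["serum_albumin"] = 0.0
    return GeneratorConfig(
        n_patients=n, beta=BETA_TRUE, tpr=1.0, fpr=0.01,
        missingness=0.0, missingness_unhealthy=miss,
        recovery_rate=recovery, seed=seed,
    )


@pytest.fixture(scope="session")
def specs():
    return load_component_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient cohort under the default (noisy) configuration."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=20240901))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort whose error-prone index equals the truth exactly."""
    cfg = GeneratorConfig(n_patients=800, beta=BETA_TRUE, tpr=1.0, fpr=0.0,
                          missingness=0.0, seed=7)
    return generate_cohort(cfg)
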