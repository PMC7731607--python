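import numpy as np
import pandas as pd
import pytest

from vbacscore import SimulationConfig, generate_cohort
from vbacscore.scoring import Indication, Outcome


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Seeded 150-patient bin-calibrated cohort (the study's sample size)."""
    return generate_cohort(SimulationConfig(n=150, seed=20180101))


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """Seeded 5,000-patient bin-calibrated cohort for distributional checks."""
    return generate_cohort(SimulationConfig(n=5000, seed=42))


def random_record_kwargs(rng: np.random.Generator) -> dict:
    """Valid admission covariates drawn uniformly over their ranges."""
    return {
        "age": float(rng.uniform(18, 35)),
        "gestational_age": float(rng.uniform(37, 42)),
        "indication": rng.choice([m.value for m in Indication]),
        "bishop": int(rng.integers(0, 11)),
        "bmi": float(rng.uniform(17, 42)),
        "efw_g": float(rng.uniform(1800, 4200)),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
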