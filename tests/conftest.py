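import numpy as np
import pandas as pd
import pytest

from growthscale.cohort import (
    NoiseParams,
    ReferenceParams,
    default_reference,
    simulate_cohort,
    true_landmarks,
)
from growthscale.pipeline import PipelineConfig, preprocess


@pytest.fixture(scope="session")
def reference():
    """Calibrated default reference parameters (k = 2.5)."""
    return default_reference()


@pytest.fixture(scope="session")
def oracle(reference):
    """Dense-grid landmark oracle on the noiseless reference curves."""
    return true_landmarks(reference)


@pytest.fixture(scope="session")
def cohort(reference):
    """Default synthetic cohort, n = 80 per sex."""
    return simulate_cohort(reference, n_per_sex=80, seed=1)


@pytest.fixture(scope="session")
def clean_cohort(cohort):
    clean, _ = preprocess(cohort, PipelineConfig())
    return clean


@pytest.fixture(scope="session")
def noiseless_reference(reference):
    """Reference parameters with every noise and random-effect SD zeroed."""
    return ReferenceParams(
        k=reference.k,
        female=reference.female,
        male=reference.male,
        noise=NoiseParams(
            sigma_weight=0.0, sigma_length=0.0, sigma_hormone=0.0,
            sd_size=0.0, sd_timing=0.0, sd_zoo=0.0, pregnant_prob=0.0,
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230905)


@pytest.fixture()
def tiny_cohort_frame():
    """Hand-built tidy frame exercising every preprocessing rule."""
    rows = [
        # three same-day weights for F001 -> daily mean 12
        ("F001", "F", "zoo00", 4.0, "weight_kg", 10.0, False, 1461),
        ("F001", "F", "zoo00", 4.0, "weight_kg", 12.0, False, 1461),
        ("F001", "F", "zoo00", 4.0, "weight_kg", 14.0, False, 1461),
        # pregnant female: weight dropped, forearm kept
        ("F002", "F", "zoo01", 12.0, "weight_kg", 36.0, True, 4383),
        ("F002", "F", "zoo01", 12.0, "forearm_cm", 26.0, True, 4383),
        # hormone record: natural-log transform
        ("M001", "M", "zoo02", 9.0, "testosterone", float(np.exp(2.0)), False, 3287),
        ("M001", "M", "zoo02", 9.0, "DHEA", 20.0, False, 3287),
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "sex", "zoo", "age_years", "variable", "value", "pregnant", "date_index"],
    )
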