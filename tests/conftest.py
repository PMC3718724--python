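import numpy as np
import pytest

from fdgquant import (CohortConfig, InputFunctionParams, TissueKinetics,
                      make_default_schedule, simulate_cohort)


@pytest.fixture(scope="session")
def schedule():
    return make_default_schedule()


@pytest.fixture(scope="session")
def nominal_input():
    """Typical bolus shape at the nominal 18.28 MBq dose."""
    return InputFunctionParams(A1=6.0e5, A2=8.0e5, A3=2.5e6,
                               mu1=0.018, mu2=0.5, mu3=3.5, mu4=7.0)


@pytest.fixture(scope="session")
def irreversible_tumor():
    return TissueKinetics(K1=0.1, k2=0.2, k3=0.05, k4=0.0, VB=0.05)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-mouse noisy cohort shared across read-only tests."""
    cfg = CohortConfig(n_mice={"U87": 3, "MDA": 3})
    return cfg, simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = CohortConfig(n_mice={"U87": 2, "MDA": 2}, noise_scale=0.0,
                       blood_sample_cv=0.0)
    return cfg, simulate_cohort(cfg, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
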