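import numpy as np
import pytest

from swaykit.config import PipelineConfig
from swaykit.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects (half HV, half PPMS), 2 trials each, deterministic."""
    subjects, trials = generate_cohort(
        8, {"HV": 0.5, "PPMS": 0.5}, n_trials=2, seed=11
    )
    return subjects, trials


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from swaykit.pipeline import compute_feature_matrices

    subjects, trials = small_cohort
    return compute_feature_matrices(subjects, trials, PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_generator():
    """Generator with sway amplitude forced to zero (pure gravity limit)."""
    return GeneratorConfig(base_sway_amp=0.0, tremor_coef=0.0, sensor_noise_sd=0.0)
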