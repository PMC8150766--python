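import numpy as np
import pytest
from hypothesis import settings

from ieegfuse.experiment import ExperimentConfig, build_dataset, run_experiment

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_config() -> ExperimentConfig:
    """Fixed study conditions for the end-to-end synthetic runs."""
    return ExperimentConfig(n_per_class=400, duration=10.0, seed=0)


@pytest.fixture(scope="session")
def study_dataset(study_config):
    """Synthetic two-class dataset (400/class, 10 s segments, seed 0)."""
    return build_dataset(study_config)


@pytest.fixture(scope="session")
def study_result(study_config, study_dataset):
    """Both branches and the fusion head trained on the study dataset."""
    return run_experiment(study_config, study_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
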