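import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small high-SNR synthetic dataset shared across pipeline tests."""
    from minav.synthetic import SyntheticConfig, generate_dataset

    config = SyntheticConfig(trial_counts=10, erd_depth=0.8, rng_seed=11)
    return generate_dataset(config), config


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """A fitted pipeline on the small dataset (reduced split sizes)."""
    from minav.classifier import TrainingConfig
    from minav.decoder import DecoderConfig, fit_offline

    trials, _ = small_dataset
    config = DecoderConfig(
        n_train=7, n_test=3, training=TrainingConfig(rng_seed=5), split_seed=5
    )
    return fit_offline(trials, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
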