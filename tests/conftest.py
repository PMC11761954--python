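import numpy as np
import pytest

from glisp.glisp_p import GlispPConfig, TrainConfig, train_glisp_p
from glisp.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort shared by fast unit tests."""
    return generate_cohort(SynthConfig(n_cases=8, slides_per_case=1,
                                       patches_per_slide=8, seed=11))


@pytest.fixture(scope="session")
def small_model_config():
    return GlispPConfig(channels=(4, 8, 8, 8), encoding_dim=16)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_cohort, small_model_config):
    """A quickly trained patch model for inference/interpretation tests."""
    model, history = train_glisp_p(
        tiny_cohort.images, tiny_cohort.manifest, tiny_cohort.labels, "idh",
        config=TrainConfig(max_epochs=2, batch_size=32, seed=5),
        model_config=small_model_config)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
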