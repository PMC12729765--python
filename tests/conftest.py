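import numpy as np
import pytest

from ceusalnm.prompts import PromptPool, PromptTemplate
from ceusalnm.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_pool():
    return PromptPool(
        templates=(
            PromptTemplate("pre", "{}, an action"),
            PromptTemplate("mid", "the disease is {}, look here"),
            PromptTemplate("post", "a video of action {}"),
        ),
        class_labels=("non-metastatic", "metastatic"),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """10 balanced synthetic patients, shared across tests (read-only)."""
    return generate_dataset(SyntheticConfig(n_patients=10, metastatic_fraction=0.5, seed=7))


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(n_patients=4, metastatic_fraction=0.5, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config)
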