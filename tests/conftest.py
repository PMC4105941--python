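import warnings

import numpy as np
import pytest

from tgfsmad import NoiseModel, assemble_model, equilibrate, generate_bundle


@pytest.fixture(scope="session")
def model1():
    m = assemble_model("1")
    equilibrate(m)
    return m


@pytest.fixture(scope="session")
def model5():
    m = assemble_model("5")
    equilibrate(m)
    return m


@pytest.fixture(scope="session")
def model8():
    m = assemble_model("8")
    equilibrate(m)
    return m


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic bundle from the final-model ground truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle("8", noise=NoiseModel(cv=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-noise bundle (cv = 0.2, n = 3) from Model-8 truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle("8", noise=NoiseModel(cv=0.2, replicates=3),
                               seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
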