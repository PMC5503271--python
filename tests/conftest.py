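import numpy as np
import pytest

from emgknee import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study dataset: 260 labelled segments."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
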