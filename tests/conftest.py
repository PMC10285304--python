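import numpy as np
import pytest

from ldntsc import synth


@pytest.fixture(scope="session")
def bump_fixture():
    """The standard separable two-class fixture: 200/100 samples, sigma 0.1."""
    return synth.generate(synth.SynthSpec(seed=42))


@pytest.fixture(scope="session")
def tiny_fixture():
    """A small fixture for fast smoke training."""
    return synth.generate(synth.SynthSpec(n_train=40, n_test=20, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
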