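import numpy as np
import pytest

from mvlda import Config, SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 lncRNAs x 10 diseases x 5 miRNAs with 2 planted blocks —
    small enough for exhaustive/loop oracles, dense enough to have
    positives in every fold."""
    ds, labels = generate(SyntheticSpec(nl=12, nd=10, nm=5, n_blocks=2,
                                        density=0.3, noise_rate=0.05, seed=1))
    return ds, labels


@pytest.fixture(scope="session")
def default_fixture():
    """The package's default synthetic study conditions."""
    return generate(SyntheticSpec())


@pytest.fixture
def fast_config():
    """A configuration small enough for seconds-long training in tests."""
    return Config(hidden=16, l1=8, l2=8, r=4, epochs=8, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
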