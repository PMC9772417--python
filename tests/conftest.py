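import numpy as np
import pytest

from bayeslimit.datasets import LabeledDataset
from bayeslimit.experiments import fig6_generative_spec, _sample_split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig6_spec():
    """Two equal-prior spherical unit Gaussians at (-1/2, 0) and (+1/2, 0)."""
    return fig6_generative_spec(1.0)


@pytest.fixture(scope="session")
def fig6_dataset(fig6_spec) -> LabeledDataset:
    """10000 balanced samples from the overlapping two-Gaussian source."""
    return _sample_split(fig6_spec, 10_000, np.random.default_rng(777))
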