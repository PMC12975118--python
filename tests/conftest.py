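import numpy as np
import pytest

from npmix.likelihood import LikelihoodMatrix


def random_likelihood(rng, n, m, scaled=True):
    """Random positive likelihood-like matrix in the package's row-scaled
    convention (row max 1, log scales recorded)."""
    raw = rng.random((n, m)) + 0.05
    if not scaled:
        return LikelihoodMatrix(L=raw, row_log_scale=np.zeros(n))
    s = raw.max(axis=1)
    return LikelihoodMatrix(L=raw / s[:, None], row_log_scale=np.log(s))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_likelihood():
    return LikelihoodMatrix(L=np.eye(2), row_log_scale=np.zeros(2))
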