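import numpy as np
import pytest

import memocf as mc


@pytest.fixture(scope="session")
def toy_bundle():
    """Small planted-structure bundle shared by read-only tests."""
    bundle, scores = mc.generate_dataset(mc.SynthSpec(30, 20, 4, 0.08, seed=11))
    return bundle, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_similarity(rng, k):
    """Random symmetric matrix in [0, 1] with unit diagonal."""
    a = rng.random((k, k))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
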