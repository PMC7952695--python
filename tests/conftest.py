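import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_survival_fixture(rng, n, event_frac=0.7, unique_times=False):
    """Small random survival dataset for oracle comparisons."""
    x = rng.standard_normal(n)
    if unique_times:
        t = rng.permutation(np.arange(1, n + 1)).astype(float)
    else:
        t = rng.exponential(20.0, n)
    e = (rng.random(n) < event_frac).astype(int)
    if e.sum() < 2:
        e[:2] = 1
    return x, t, e
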