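import numpy as np
import pytest

import pgsmediate as pm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_network(rng, n, density=0.7):
    """Random weighted undirected graph with weights in (0, 1)."""
    w = rng.uniform(0.05, 1.0, (n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w


@pytest.fixture
def small_cohort():
    cfg = pm.CohortConfig(
        n_participants=80,
        n_snps=300,
        n_causal_snps=40,
        n_rois=16,
        mediator_rois=(2, 7),
        bands=("theta",),
        seed=7,
    )
    return pm.simulate_cohort(cfg)
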