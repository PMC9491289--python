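import numpy as np
import pytest

import richclubkit as rk


def make_connectome(W, subject_id="s", group="HC", binary=False):
    W = np.asarray(W, dtype=float)
    return rk.Connectome(subject_id=subject_id, group=group, W=W, binary=binary)


def from_edges(n, edges, subject_id="s", group="HC"):
    """Build a connectome from (i, j, w) triples."""
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return make_connectome(W, subject_id=subject_id, group=group)


def random_weighted(n, p, rng, low=1, high=100):
    A = np.triu(rng.random((n, n)) < p, k=1)
    W = np.where(A, rng.integers(low, high, size=(n, n)).astype(float), 0.0)
    W = W + W.T
    return make_connectome(W)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject two-group synthetic cohort at N=60, thresholded."""
    spec = rk.SyntheticSpec(n_nodes=60)
    cohort, truth = rk.generate_cohort(spec, {"HC": 5, "OCD": 5}, seed=7)
    built, report = rk.construct_cohort(cohort, 0.23, 0.60)
    return built, truth, report
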