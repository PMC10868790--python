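import numpy as np
import pytest

from connscale import CohortSpec, generate_connectome


def random_weighted_graph(n, density, rng, connected=True):
    """Random symmetric weighted graph with positive continuous weights."""
    for _ in range(50):
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        present = rng.uniform(size=len(iu[0])) < density
        vals = rng.lognormal(0.0, 0.5, size=present.sum())
        w[iu[0][present], iu[1][present]] = vals
        w += w.T
        if not connected:
            return w
        from scipy.sparse.csgraph import connected_components
        import scipy.sparse as sp

        if connected_components(sp.csr_matrix(w), directed=False)[0] == 1:
            return w
    raise RuntimeError("failed to draw a connected graph")


def sbm_graph(n, n_blocks, p_in, p_out, rng):
    """Binary stochastic block model with equal blocks."""
    labels = np.repeat(np.arange(n_blocks), n // n_blocks)
    labels = np.concatenate([labels, np.full(n - len(labels), n_blocks - 1)])
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    p = np.where(same, p_in, p_out)
    present = rng.uniform(size=len(p)) < p
    w[iu[0][present], iu[1][present]] = 1.0
    return w + w.T, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return CohortSpec(n_animals=5, n_nodes=60, seed=11)


@pytest.fixture
def small_bundle(small_spec):
    return generate_connectome(1.0, small_spec, seed=42)
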