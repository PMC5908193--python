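import numpy as np
import pytest

from scvdmc import ExpressionDomain, MultiDomainDataset


def make_dataset(rng, m=6, k=3, D=2, n=12, scale=1.0):
    """Random multi-domain dataset with mild cluster structure."""
    centers = scale * rng.normal(size=(m, k)) * 3.0
    domains = []
    for d in range(D):
        labels = rng.integers(0, k, size=n)
        # guarantee every cluster occupied so V has no empty columns
        labels[:k] = np.arange(k)
        X = centers[:, labels] + rng.normal(size=(m, n))
        domains.append(
            ExpressionDomain(f"d{d}", X, [f"d{d}c{i}" for i in range(n)])
        )
    return MultiDomainDataset([f"g{i}" for i in range(m)], domains)


def random_state(rng, dataset, k, lam=None):
    """Random valid (U, V, B) for a dataset: one-hot V without empty columns,
    arbitrary centers, B with lam ones."""
    m, D = dataset.n_genes, dataset.n_domains
    U, V = [], []
    for dom in dataset.domains:
        n = dom.n_cells
        labels = rng.integers(0, k, size=n)
        labels[:k] = rng.permutation(k)
        Vd = np.zeros((n, k), dtype=int)
        Vd[np.arange(n), labels] = 1
        V.append(Vd)
        U.append(rng.normal(size=(m, k)))
    lam = lam if lam is not None else rng.integers(1, m + 1)
    B = np.zeros(m, dtype=int)
    B[rng.choice(m, size=lam, replace=False)] = 1
    return U, V, B


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def state_factory():
    return random_state
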