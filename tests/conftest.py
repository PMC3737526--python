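import numpy as np
import pytest

from ipcc import ExpressionMatrix


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Independent scalar Pearson oracle: the textbook centred-dot formula."""
    xc = x - sum(x) / len(x)
    yc = y - sum(y) / len(y)
    num = sum(a * b for a, b in zip(xc, yc))
    den = (sum(a * a for a in xc) ** 0.5) * (sum(b * b for b in yc) ** 0.5)
    return num / den


def naive_pairwise(rows: np.ndarray) -> np.ndarray:
    """Per-pair loop correlation matrix of the rows of ``rows``."""
    m = rows.shape[0]
    out = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = naive_pearson(rows[i], rows[j])
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_expression(rng):
    def make(n_genes=20, m_samples=10, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        values = r.normal(size=(n_genes, m_samples))
        return ExpressionMatrix(
            values=values,
            gene_ids=[f"g{i}" for i in range(n_genes)],
            sample_ids=[f"s{j}" for j in range(m_samples)],
        )

    return make
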