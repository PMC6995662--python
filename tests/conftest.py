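import numpy as np
import pandas as pd
import pytest

from smokesig.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort: 30+40 samples, 300 genes, 8 planted per layer."""
    cfg = CohortConfig(
        n_never=30,
        n_current=40,
        n_genes=300,
        n_signature_ge=8,
        n_signature_me=8,
        n_signature_cnv=8,
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference design: 59+82 samples, 2000 genes, 40 planted per layer."""
    cfg = CohortConfig(seed=1, structure_seed=1)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_two_class(n_genes, n1, n0, d_planted=0.0, n_planted=0, seed=0):
    """Plain Gaussian genes x samples matrix with an optional planted shift."""
    r = np.random.default_rng(seed)
    X = r.normal(0.0, 1.0, size=(n_genes, n1 + n0))
    labels = np.array([1.0] * n1 + [0.0] * n0)
    X[:n_planted, :n1] += d_planted
    idx = pd.Index([f"G{i:04d}" for i in range(n_genes)], name="symbol")
    return pd.DataFrame(X, index=idx), labels
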