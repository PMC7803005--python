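import numpy as np
import pytest

from rodeo import BulkMatrix, ProportionMatrix, SignatureMatrix, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-noise dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_genes=200, n_samples=40, n_batch_genes=8, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_exact_instance(n_genes=20, n_celltypes=3, n_samples=12, seed=0):
    """Noise-free E = S @ C with strictly positive S and full-row-rank C."""
    rng = np.random.default_rng(seed)
    S = rng.uniform(1.0, 50.0, size=(n_genes, n_celltypes))
    C = rng.dirichlet(np.ones(n_celltypes) * 5, size=n_samples).T
    genes = [f"g{i}" for i in range(n_genes)]
    cts = [f"ct{t}" for t in range(n_celltypes)]
    samples = [f"s{j}" for j in range(n_samples)]
    E = BulkMatrix(S @ C, genes, samples)
    return (
        SignatureMatrix(S, genes, cts),
        ProportionMatrix(C, cts, samples),
        E,
    )
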