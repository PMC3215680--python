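import numpy as np
import pytest

from prodige import (
    AssociationTable,
    DiseaseIndex,
    FeatureTable,
    GeneIndex,
    KernelMatrix,
    linear_kernel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng, ids, scale=1.0):
    """Random PSD kernel with strictly positive diagonal."""
    n = len(ids)
    X = rng.standard_normal((n, n + 2)) * scale
    K = X @ X.T
    return KernelMatrix(index=GeneIndex(ids), values=(K + K.T) / 2.0)


@pytest.fixture
def gene_ids():
    return [f"g{i}" for i in range(6)]


@pytest.fixture
def small_kernel(rng, gene_ids):
    return random_psd_kernel(rng, gene_ids)


@pytest.fixture
def planted_2d_toy():
    """20 items in 2-D: 5 labeled positives near (1,1), 10 hidden positives
    near (1,1), 5 negatives near (-1,-1); linear kernel."""
    rng = np.random.default_rng(7)
    pos = rng.normal([1.0, 1.0], 0.25, size=(5, 2))
    hidden = rng.normal([1.0, 1.0], 0.25, size=(10, 2))
    neg = rng.normal([-1.0, -1.0], 0.25, size=(5, 2))
    X = np.vstack([pos, hidden, neg])
    ids = GeneIndex([f"x{i}" for i in range(20)])
    K = linear_kernel(FeatureTable(index=ids, values=X))
    return {
        "kernel": K,
        "positives": np.arange(5),
        "hidden": np.arange(5, 15),
        "negatives": np.arange(15, 20),
        "unlabeled": np.arange(5, 20),
    }


@pytest.fixture
def tiny_instance():
    """3 diseases x 12 genes with block-structured similarity."""
    rng = np.random.default_rng(42)
    genes = GeneIndex([f"g{i:02d}" for i in range(12)])
    diseases = DiseaseIndex(["dA", "dB", "dC"])
    centers = np.array([[2.0, 0.0], [0.0, 2.0], [-2.0, -1.5]])
    X = np.vstack([centers[i // 4] + 0.3 * rng.standard_normal(2) for i in range(12)])
    K = linear_kernel(FeatureTable(index=genes, values=X))
    pairs = tuple(
        (diseases.ids[d], genes.ids[d * 4 + j]) for d in range(3) for j in range(2)
    )
    assoc = AssociationTable(pairs, genes, diseases)
    return {"genes": genes, "diseases": diseases, "kernel": K, "assoc": assoc}
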