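"""Fully in-silico benchmarks with planted disease-gene structure.

The generator emulates the statistical assumption underlying similarity-
based gene prioritization: genes causing the same disease cluster in
feature space, and phenotypically similar diseases are caused by similar
genes.  Each disease receives a centroid direction in every feature source;
its causal genes are Gaussian draws around that centroid, background genes
are draws around the origin.  Disease centroids are built from shared
latent factors with mixing weight ``phenotype_informativeness``, and the
phenotype-similarity matrix is the (noisy) correlation of those centroids -
so at informativeness 0 the phenotype matrix carries no usable information
about which diseases share gene neighborhoods, and at 1 it is maximally
informative.  A fraction of diseases can be made orphans: all their genes
are moved to a hidden truth table and none are visible at training time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model_io import AssociationTable, DiseaseIndex, GeneIndex
from .disease_kernels import PhenotypeSimilarity
from .evaluation import LOOCVResult
from .gene_kernels import FeatureTable, InteractionGraph

__all__ = ["SyntheticConfig", "SyntheticBenchmark", "generate", "random_baseline"]

_LATENT_DIM = 4
_PHENOTYPE_NOISE = 0.05
_EDGE_BASE_PROB = 0.01
_EDGE_MAX_PROB = 0.30


@dataclass
class SyntheticConfig:
    """Knobs of the planted benchmark.

    signal_strength is the distance of a disease's gene centroid from the
    origin in units of the per-source noise; 0 removes all planted signal.
    phenotype_informativeness in [0, 1] mixes shared latent factors into the
    disease centroids, controlling how predictive the phenotype matrix is of
    shared gene neighborhoods.
    """

    n_genes: int = 200
    n_diseases: int = 10
    genes_per_disease: int = 5
    n_sources: int = 2
    feature_dim: int = 10
    signal_strength: float = 3.0
    source_noise: float = 1.0
    phenotype_informativeness: float = 0.7
    orphan_fraction: float = 0.0
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_diseases", "genes_per_disease", "n_sources",
                     "feature_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.signal_strength < 0 or self.source_noise < 0:
            raise ValueError("signal_strength and source_noise must be >= 0")
        if not 0.0 <= self.phenotype_informativeness <= 1.0:
            raise ValueError("phenotype_informativeness must lie in [0, 1]")
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise ValueError("orphan_fraction must lie in [0, 1]")
        if (not self.allow_overlap and
                self.genes_per_disease * self.n_diseases > self.n_genes):
            raise ValueError(
                "no-overlap mode needs n_genes >= n_diseases * genes_per_disease"
            )


@dataclass
class SyntheticBenchmark:
    """A generated benchmark: inputs plus the hidden truth for scoring."""

    config: SyntheticConfig
    genes: GeneIndex
    diseases: DiseaseIndex
    feature_tables: list[FeatureTable]
    graph: InteractionGraph
    phenotype: PhenotypeSimilarity
    associations: AssociationTable  # visible training positives
    hidden_truth: tuple[tuple[str, str], ...]  # held-out true associations

    def __post_init__(self):
        visible = set(self.associations.pairs)
        if visible & set(self.hidden_truth):
            raise ValueError("hidden truth overlaps visible associations")


def generate(config: SyntheticConfig) -> SyntheticBenchmark:
    """Draw one benchmark; same config (including seed) is bit-reproducible."""
    rng = np.random.default_rng(config.seed)
    m, n = config.n_diseases, config.n_genes
    genes = GeneIndex([f"g{i:04d}" for i in range(n)])
    diseases = DiseaseIndex([f"d{i:03d}" for i in range(m)])

    # disease centroid directions, correlated through shared latent factors
    latent = rng.standard_normal((m, _LATENT_DIM))
    rho = config.phenotype_informativeness
    centroids = []  # per source: m x feature_dim unit rows
    for _ in range(config.n_sources):
        A = rng.standard_normal((_LATENT_DIM, config.feature_dim)) / np.sqrt(_LATENT_DIM)
        own = rng.standard_normal((m, config.feature_dim))
        c = np.sqrt(rho) * (latent @ A) + np.sqrt(1.0 - rho) * own
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        centroids.append(c)

    # disease gene sets
    members: list[np.ndarray] = []
    if config.allow_overlap:
        for _ in range(m):
            members.append(rng.choice(n, size=config.genes_per_disease, replace=False))
    else:
        perm = rng.permutation(n)
        for i in range(m):
            members.append(
                perm[i * config.genes_per_disease:(i + 1) * config.genes_per_disease]
            )

    disease_of_gene: dict[int, list[int]] = {}
    for d, gs in enumerate(members):
        for g in gs:
            disease_of_gene.setdefault(int(g), []).append(d)

    feature_tables = []
    for s in range(config.n_sources):
        X = config.source_noise * rng.standard_normal((n, config.feature_dim))
        for g, ds in disease_of_gene.items():
            direction = centroids[s][ds].mean(axis=0)
            X[g] += config.signal_strength * config.source_noise * direction
        feature_tables.append(
            FeatureTable(index=genes, values=X, source_name=f"source{s}")
        )

    # phenotype similarity: correlation of concatenated centroids plus noise
    stacked = np.hstack(centroids)
    stacked = stacked - stacked.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(stacked, axis=1, keepdims=True)
    S = (stacked / norms) @ (stacked / norms).T
    noise = rng.standard_normal((m, m)) * _PHENOTYPE_NOISE
    S = S + (noise + noise.T) / 2.0
    np.fill_diagonal(S, 1.0)
    phenotype = PhenotypeSimilarity(index=diseases, values=S)

    # interaction graph: edge probability increasing in feature similarity
    Xc = np.hstack([t.values for t in feature_tables])
    norm = np.linalg.norm(Xc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    cos = (Xc / norm) @ (Xc / norm).T
    prob = _EDGE_BASE_PROB + (_EDGE_MAX_PROB - _EDGE_BASE_PROB) * (cos + 1.0) / 2.0
    draws = rng.random((n, n))
    iu = np.triu_indices(n, k=1)
    sel = draws[iu] < prob[iu]
    edges = tuple(
        (genes.ids[i], genes.ids[j])
        for i, j in zip(iu[0][sel], iu[1][sel])
    )
    graph = InteractionGraph(index=genes, edges=edges, source_name="synthetic-ppi")

    # orphan split: chosen diseases contribute all their genes to hidden truth
    n_orphans = int(round(config.orphan_fraction * m))
    orphan_ds = set(rng.choice(m, size=n_orphans, replace=False).tolist())
    visible, hidden = [], []
    for d, gs in enumerate(members):
        for g in gs:
            pair = (diseases.ids[d], genes.ids[int(g)])
            (hidden if d in orphan_ds else visible).append(pair)
    if not visible:
        raise ValueError("orphan_fraction leaves no visible associations")
    assoc = AssociationTable(tuple(visible), genes, diseases)
    return SyntheticBenchmark(
        config=config,
        genes=genes,
        diseases=diseases,
        feature_tables=feature_tables,
        graph=graph,
        phenotype=phenotype,
        associations=assoc,
        hidden_truth=tuple(hidden),
    )


def random_baseline(
    result: LOOCVResult, n_draws: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null distribution of the mean rank under uniform random ranking.

    Each held-out gene's rank is drawn uniformly on {1, ..., n_candidates};
    returns the ``n_draws`` Monte-Carlo means.
    """
    if not len(result):
        raise ValueError("empty LOOCV result")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, len(result)))
    for j, n_c in enumerate(result.n_candidates):
        draws[:, j] = rng.integers(1, int(n_c) + 1, size=n_draws)
    return draws.mean(axis=1)
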