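"""Assemble disease-gene pair kernels and produce per-disease gene rankings.

The multitask formulation scores *pairs* (D, G) with the tensor-product
kernel

    K_pair((D, G), (D', G')) = K_disease(D, D') * K_gene(G, G'),

trains the PU engine on the known disease-gene pairs against subsamples of
unknown pairs, and ranks the candidate genes of a query disease by the
decreasing score of their pairs with that disease.  The pair kernel is
served lazily, block by block; the full (M*N)^2 Gram is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .data_model_io import (
    AssociationTable,
    DiseaseIndex,
    GeneIndex,
    KernelMatrix,
    RankingTable,
    RunConfig,
)
from .disease_kernels import PhenotypeSimilarity, disease_kernel_for_variant
from .gene_kernels import fuse_kernels
from .pu_engine import PUProblem, fit_pu_model

__all__ = [
    "PairIndex",
    "LazyPairKernel",
    "pairwise_kernel",
    "candidate_set",
    "rank_genes",
]


@dataclass
class PairIndex:
    """An ordered list of (disease, gene) pairs as positions in their indices."""

    diseases: DiseaseIndex
    genes: GeneIndex
    d_pos: np.ndarray  # disease position of each pair
    g_pos: np.ndarray  # gene position of each pair

    def __post_init__(self):
        self.d_pos = np.asarray(self.d_pos, dtype=np.intp)
        self.g_pos = np.asarray(self.g_pos, dtype=np.intp)
        if self.d_pos.shape != self.g_pos.shape:
            raise ValueError("disease and gene position arrays must align")

    def __len__(self):
        return self.d_pos.size

    def pair_ids(self) -> list[tuple[str, str]]:
        return [
            (self.diseases.ids[d], self.genes.ids[g])
            for d, g in zip(self.d_pos, self.g_pos)
        ]


@dataclass
class LazyPairKernel:
    """Tensor-product pair kernel served block-wise over an enumerated PairIndex."""

    K_disease: KernelMatrix
    K_gene: KernelMatrix
    pairs: PairIndex

    def __post_init__(self):
        if self.pairs.d_pos.size and self.pairs.d_pos.max() >= len(self.K_disease.index):
            raise IndexError("pair disease position outside disease kernel")
        if self.pairs.g_pos.size and self.pairs.g_pos.max() >= len(self.K_gene.index):
            raise IndexError("pair gene position outside gene kernel")

    @property
    def n_items(self) -> int:
        return len(self.pairs)

    @property
    def item_labels(self) -> tuple[str, ...]:
        return tuple(f"{d}|{g}" for d, g in self.pairs.pair_ids())

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr, dc = self.pairs.d_pos[rows], self.pairs.d_pos[cols]
        gr, gc = self.pairs.g_pos[rows], self.pairs.g_pos[cols]
        Kd = self.K_disease.values[np.ix_(dr, dc)]
        Kg = self.K_gene.values[np.ix_(gr, gc)]
        return Kd * Kg


def pairwise_kernel(
    K_disease: KernelMatrix,
    K_gene: KernelMatrix,
    rows: PairIndex,
    cols: PairIndex,
) -> np.ndarray:
    """Dense block of the tensor-product pair kernel between two pair lists."""
    Kd = K_disease.values[np.ix_(rows.d_pos, cols.d_pos)]
    Kg = K_gene.values[np.ix_(rows.g_pos, cols.g_pos)]
    return Kd * Kg


def candidate_set(
    genes: GeneIndex,
    assoc: AssociationTable,
    query: str,
    shortlist: list[str] | None = None,
) -> list[str]:
    """Candidate genes for a query disease: the complement of its positives.

    A user-supplied shortlist replaces the full complement (its training
    positives are still removed).  Candidates are returned in gene-index
    order.
    """
    if query not in assoc.diseases:
        raise KeyError(f"unknown disease {query!r}")
    pos = assoc.positive_set(query)
    if shortlist is not None:
        for g in shortlist:
            if g not in genes:
                raise KeyError(f"shortlist gene {g!r} not in gene index")
        keep = set(shortlist) - pos
        if not keep:
            raise ValueError("shortlist is entirely contained in the training positives")
        return [g for g in genes.ids if g in keep]
    return [g for g in genes.ids if g not in pos]


def _mid_ranks(scores: np.ndarray, tie_rule: str) -> np.ndarray:
    method = "average" if tie_rule == "mid" else "max"
    return scipy.stats.rankdata(-scores, method=method)


def rank_genes(
    variant: int,
    genes: GeneIndex,
    gene_kernels: list[KernelMatrix],
    assoc: AssociationTable,
    phenotype: PhenotypeSimilarity | None,
    query: str,
    candidates: list[str] | str = "auto",
    config: RunConfig | None = None,
    fused_gene_kernel: KernelMatrix | None = None,
) -> RankingTable:
    """Rank candidate genes for one query disease under a given variant.

    Gene kernels are fused by unit-diagonal normalization followed by
    averaging (pass ``fused_gene_kernel`` to reuse a fusion across calls,
    e.g. inside cross-validation).  Variant 1 requires training positives
    for the query disease; an orphan query under variant 4 falls back to the
    pure phenotype kernel of variant 3, with which it provably shares its
    scoring function in that setting.
    """
    config = config or RunConfig(variant=variant)
    Kg = fused_gene_kernel if fused_gene_kernel is not None else fuse_kernels(gene_kernels)
    if Kg.index != genes:
        raise ValueError("fused gene kernel index does not match the gene index")
    shortlist = None if candidates == "auto" else list(candidates)
    cand = candidate_set(genes, assoc, query, shortlist)
    q_pos = assoc.positive_set(query)
    diseases = assoc.diseases

    if variant == 1:
        if not q_pos:
            raise ValueError(
                f"variant 1 treats diseases independently and requires known "
                f"disease genes; none for orphan query {query!r}"
            )
        # Dirac block separation: with a no-intercept SVM the pair problem
        # decomposes by disease, so only the query's block is assembled.
        d_sub = DiseaseIndex([query])
        Kd = disease_kernel_for_variant(1, d_sub)
        pos_genes = [g for g in genes.ids if g in q_pos]
        all_genes = pos_genes + cand
        g_pos_arr = genes.positions(all_genes)
        pairs = PairIndex(d_sub, genes, np.zeros(len(all_genes), dtype=np.intp), g_pos_arr)
        kernel = LazyPairKernel(Kd, Kg, pairs)
        positives = np.arange(len(pos_genes))
        unlabeled = np.arange(len(pos_genes), len(all_genes))
        query_positions = unlabeled
        # single-disease pair items are identified by their gene alone, so
        # subsampling matches a direct run of the engine on the gene kernel
        item_labels: list[str] | None = list(all_genes)
    else:
        effective_variant = variant
        if variant == 4 and not q_pos:
            effective_variant = 3  # Dirac contribution vanishes for orphan queries
        Kd = disease_kernel_for_variant(effective_variant, diseases, phenotype)
        # positive pairs: all training associations, enumerated canonically
        pos_d, pos_g = [], []
        for d in diseases.ids:
            for g in assoc.positives.get(d, ()):
                pos_d.append(diseases.position(d))
                pos_g.append(genes.position(g))
        # unlabeled pool: (D_j, G) for D_j in training diseases + query, G not
        # a known positive of D_j
        pool_diseases = [d for d in diseases.ids if assoc.positives.get(d)]
        if query not in pool_diseases:
            pool_diseases.append(query)
        unl_d, unl_g = [], []
        for d in pool_diseases:
            pset = assoc.positive_set(d)
            dp = diseases.position(d)
            for gp, g in enumerate(genes.ids):
                if g not in pset:
                    unl_d.append(dp)
                    unl_g.append(gp)
        d_pos_arr = np.asarray(pos_d + unl_d, dtype=np.intp)
        g_pos_arr = np.asarray(pos_g + unl_g, dtype=np.intp)
        pairs = PairIndex(diseases, genes, d_pos_arr, g_pos_arr)
        kernel = LazyPairKernel(Kd, Kg, pairs)
        positives = np.arange(len(pos_d))
        unlabeled = np.arange(len(pos_d), len(pairs))
        # locate the query's candidate pairs within the pool enumeration
        qp = diseases.position(query)
        lookup = {
            (int(d), int(g)): i
            for i, (d, g) in enumerate(zip(d_pos_arr, g_pos_arr))
            if i >= len(pos_d)
        }
        query_positions = np.asarray(
            [lookup[(qp, int(genes.position(g)))] for g in cand], dtype=np.intp
        )
        item_labels = None  # pair identities from the lazy kernel

    problem = PUProblem(
        kernel=kernel, positives=positives, unlabeled=unlabeled, labels=item_labels
    )
    size = "auto" if config.subsample_size == "auto" else int(config.subsample_size)
    model = fit_pu_model(problem, B=config.B, subsample_size=size, C=config.C,
                         seed=config.seed)
    scores, _ = model.score_items(query_positions)

    if config.include_training and q_pos:
        train_genes = [g for g in genes.ids if g in q_pos]
        if variant == 1:
            train_pos = np.arange(len(train_genes))
        else:
            qp = diseases.position(query)
            pos_lookup = {
                (int(d), int(g)): i
                for i, (d, g) in enumerate(
                    zip(pairs.d_pos[: len(positives)], pairs.g_pos[: len(positives)])
                )
            }
            train_pos = np.asarray(
                [pos_lookup[(qp, int(genes.position(g)))] for g in train_genes],
                dtype=np.intp,
            )
        extra, _ = model.score_items(train_pos)
        cand = cand + train_genes
        scores = np.concatenate([scores, extra])

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    ranks = _mid_ranks(sorted_scores, config.tie_rule)
    return RankingTable(
        disease_id=query,
        gene_ids=tuple(cand[i] for i in order),
        scores=sorted_scores,
        ranks=ranks,
    )
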