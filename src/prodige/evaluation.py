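"""Leave-one-out evaluation, rank statistics, recall curves and tests.

Each known (disease, gene) association is removed in turn, the model is
retrained on the remaining pairs, and the held-out gene is ranked among the
disease's candidates (which it rejoins for the evaluation).  The rank of the
left-out gene relates to the ROC AUC through rank = (|U| + 1) * (1 - AUC),
so the empirical CDF of the ranks doubles as a recall-at-k curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .data_model_io import (
    AssociationTable,
    GeneIndex,
    KernelMatrix,
    RunConfig,
)
from .disease_kernels import PhenotypeSimilarity
from .gene_kernels import fuse_kernels
from .prioritizer import rank_genes

__all__ = [
    "LOOCVResult",
    "RecallCurve",
    "rank_of",
    "auc_from_rank",
    "loocv",
    "orphan_ranks",
    "recall_curve",
    "wilcoxon_paired",
    "hypergeom_enrichment",
    "overlap_stats",
]


@dataclass
class LOOCVResult:
    """Per-held-out-association ranks from leave-one-out cross-validation."""

    disease_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    ranks: np.ndarray
    n_candidates: np.ndarray
    variant: int = 0
    config: RunConfig | None = None

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=float)
        self.n_candidates = np.asarray(self.n_candidates, dtype=int)
        k = len(self.disease_ids)
        if not (k == len(self.gene_ids) == self.ranks.size == self.n_candidates.size):
            raise ValueError("result columns must have equal length")
        if k and (np.any(self.ranks < 1) or np.any(self.ranks > self.n_candidates)):
            raise ValueError("every rank must lie in [1, n_candidates]")

    def __len__(self):
        return len(self.disease_ids)

    @property
    def mean_rank(self) -> float:
        return float(self.ranks.mean())

    @property
    def median_rank(self) -> float:
        return float(np.median(self.ranks))


@dataclass
class RecallCurve:
    """Recall (rank CDF) evaluated on a grid of rank thresholds."""

    grid: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.grid) != self.values.size:
            raise ValueError("one recall value per grid point required")

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.grid, self.values)}


def rank_of(scores: dict[str, float], target: str, tie_rule: str = "mid") -> float:
    """Rank of the target item within a score mapping (rank 1 = best).

    mid rule: #{strictly greater} + (#{tied, incl. target} + 1) / 2;
    worst rule: #{greater or tied, excl. target} + 1.
    """
    if target not in scores:
        raise KeyError(f"target {target!r} has no score")
    t = scores[target]
    vals = np.asarray(list(scores.values()), dtype=float)
    greater = int(np.sum(vals > t))
    tied = int(np.sum(vals == t))  # includes the target itself
    if tie_rule == "mid":
        return greater + (tied + 1) / 2.0
    if tie_rule == "worst":
        return float(greater + tied)
    raise ValueError("tie_rule must be 'mid' or 'worst'")


def auc_from_rank(rank: float, n_candidates: int) -> float:
    """AUC implied by the rank of the single left-out positive.

    Inverts rank = n_candidates * (1 - AUC), with n_candidates the size of
    the ranked list including the target (|U| + 1).
    """
    if not (1 <= rank <= n_candidates):
        raise ValueError(f"rank {rank} outside [1, {n_candidates}]")
    return 1.0 - rank / n_candidates


def loocv(
    variant: int,
    genes: GeneIndex,
    gene_kernels: list[KernelMatrix],
    assoc: AssociationTable,
    phenotype: PhenotypeSimilarity | None,
    config: RunConfig | None = None,
) -> LOOCVResult:
    """Leave-one-out cross-validation over all known associations.

    For each pair the model is retrained on the T - 1 remaining pairs and
    the held-out gene is ranked among U union {held-out gene}.  Variant 1
    cannot rescore a disease left with no positives, so it requires every
    disease in the table to have at least two known genes.
    """
    config = config or RunConfig(variant=variant)
    if variant == 1:
        lonely = sorted(d for d, gs in assoc.positives.items() if len(gs) < 2)
        if lonely:
            raise ValueError(
                "variant 1 requires >= 2 known genes per evaluated disease; "
                f"offending diseases: {lonely}"
            )
    fused = fuse_kernels(gene_kernels)
    d_ids, g_ids, ranks, n_cands = [], [], [], []
    # canonical association order: by (disease position, gene position)
    ordered = sorted(
        assoc.pairs,
        key=lambda p: (assoc.diseases.position(p[0]), assoc.genes.position(p[1])),
    )
    for d, g in ordered:
        reduced = assoc.without(d, g)
        table = rank_genes(
            variant,
            genes,
            gene_kernels,
            reduced,
            phenotype,
            query=d,
            candidates="auto",
            config=config,
            fused_gene_kernel=fused,
        )
        d_ids.append(d)
        g_ids.append(g)
        ranks.append(table.rank_of(g))
        n_cands.append(len(table))
    return LOOCVResult(
        disease_ids=tuple(d_ids),
        gene_ids=tuple(g_ids),
        ranks=np.asarray(ranks),
        n_candidates=np.asarray(n_cands),
        variant=variant,
        config=config,
    )


def orphan_ranks(
    variant: int,
    genes: GeneIndex,
    gene_kernels: list[KernelMatrix],
    assoc: AssociationTable,
    phenotype: PhenotypeSimilarity | None,
    hidden: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> LOOCVResult:
    """Rank hidden true genes of orphan diseases (no visible positives).

    Requires a variant that shares information across diseases (2, 3 or 4).
    Every gene is a candidate for an orphan disease, so n_candidates = N.
    """
    if variant == 1:
        raise ValueError(
            "variant 1 treats diseases independently and cannot rank orphan diseases"
        )
    config = config or RunConfig(variant=variant)
    fused = fuse_kernels(gene_kernels)
    d_ids, g_ids, ranks, n_cands = [], [], [], []
    orphan_diseases = sorted(
        {d for d, _ in hidden}, key=lambda d: assoc.diseases.position(d)
    )
    for d in orphan_diseases:
        if assoc.positive_set(d):
            raise ValueError(f"disease {d!r} has visible positives; not an orphan")
        table = rank_genes(
            variant,
            genes,
            gene_kernels,
            assoc,
            phenotype,
            query=d,
            candidates="auto",
            config=config,
            fused_gene_kernel=fused,
        )
        for dd, g in hidden:
            if dd != d:
                continue
            d_ids.append(d)
            g_ids.append(g)
            ranks.append(table.rank_of(g))
            n_cands.append(len(table))
    return LOOCVResult(
        disease_ids=tuple(d_ids),
        gene_ids=tuple(g_ids),
        ranks=np.asarray(ranks),
        n_candidates=np.asarray(n_cands),
        variant=variant,
        config=config,
    )


def _resolve_threshold(threshold: str | float, n_candidates: np.ndarray) -> np.ndarray:
    """Rank threshold per row; percent strings resolve against each row's list size."""
    if isinstance(threshold, str) and threshold.strip().endswith("%"):
        frac = float(threshold.strip()[:-1]) / 100.0
        return np.maximum(1, np.floor(frac * n_candidates + 1e-9))
    return np.full(n_candidates.shape, float(threshold))


def recall_curve(result: LOOCVResult, grid: list) -> RecallCurve:
    """Fraction of held-out genes ranked within each threshold of the grid.

    Integer thresholds are absolute ranks; strings like '5%' are resolved
    per association against its own candidate-list size.
    """
    if not len(result):
        raise ValueError("empty LOOCV result")
    if not grid:
        raise ValueError("empty threshold grid")
    values = []
    for threshold in grid:
        thr = _resolve_threshold(threshold, result.n_candidates)
        values.append(float(np.mean(result.ranks <= thr)))
    return RecallCurve(grid=tuple(str(s) for s in grid), values=np.asarray(values))


def wilcoxon_paired(
    ranks_a: np.ndarray, ranks_b: np.ndarray
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test between paired rank vectors.

    Zero differences are dropped (classical convention); the null
    distribution is enumerated exactly for n <= 25 pairs and approximated
    normally (with continuity correction) above.  Returns the statistic, the
    two-sided p-value and which method had the smaller (better) ranks.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 1:
        raise ValueError("need at least one pair")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return 0.0, 1.0, "none"
    s = np.sum(np.sign(diff))
    direction = "a" if s < 0 else ("b" if s > 0 else "none")
    method = "exact" if nz.size <= 25 else "approx"
    stat, p = scipy.stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(stat), float(p), direction


def hypergeom_enrichment(
    top_k: list[str], reference: list[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric enrichment of a top-k list in a reference set.

    P(X >= overlap) for X hypergeometric with population ``universe_size``,
    |reference| successes and |top_k| draws.  Training positives should be
    removed from both lists (and from the universe count) by the caller.
    """
    top = set(top_k)
    ref = set(reference)
    if universe_size < len(top | ref):
        raise ValueError("universe smaller than the union of the two gene lists")
    overlap = len(top & ref)
    return float(
        scipy.stats.hypergeom.sf(overlap - 1, universe_size, len(ref), len(top))
    )


def overlap_stats(top_k: list[str], reference: list[str]) -> tuple[float, float]:
    """(precision, recall) of a top-k list against a reference gene list."""
    top = set(top_k)
    ref = set(reference)
    if not top or not ref:
        raise ValueError("both gene lists must be non-empty")
    overlap = len(top & ref)
    return overlap / len(top), overlap / len(ref)
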