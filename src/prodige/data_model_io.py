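"""Core identifiers, tables, matrix containers and file readers/writers.

The on-disk dialect for square matrices and feature tables is tab-delimited
text: the first row carries column labels, the first cell of every following
row carries the row label.  An HDF5 backend (``.h5``/``.hdf5``) sits behind
the same reader/writer contract for large matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("prodige")

__all__ = [
    "GeneIndex",
    "DiseaseIndex",
    "KernelMatrix",
    "AssociationTable",
    "RankingTable",
    "RunConfig",
    "FormatError",
    "read_square_matrix",
    "write_square_matrix",
    "read_feature_table",
    "read_edge_list",
    "read_associations",
    "write_associations",
    "read_ranking",
    "write_ranking",
]

SYMMETRY_TOL = 1e-8
PSD_REL_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


class _IdIndex:
    """Ordered list of unique identifier strings with O(1) position lookup.

    The order is canonical: row/column ``i`` of every matrix sharing this
    index refers to ``ids[i]``.
    """

    __slots__ = ("ids", "_pos")

    def __init__(self, ids: Iterable[str]):
        ids = tuple(str(i) for i in ids)
        if not ids:
            raise ValueError("index must contain at least one identifier")
        if any(i == "" for i in ids):
            raise ValueError("identifiers must be non-empty")
        pos = {g: k for k, g in enumerate(ids)}
        if len(pos) != len(ids):
            dup = [g for g in pos if ids.count(g) > 1]
            raise ValueError(f"duplicate identifiers: {dup[:5]}")
        self.ids = ids
        self._pos = pos

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self._pos

    def __eq__(self, other) -> bool:
        return isinstance(other, _IdIndex) and self.ids == other.ids

    def __hash__(self):
        return hash(self.ids)

    def position(self, item: str) -> int:
        try:
            return self._pos[item]
        except KeyError:
            raise KeyError(f"unknown identifier {item!r}") from None

    def positions(self, items: Iterable[str]) -> np.ndarray:
        return np.asarray([self.position(i) for i in items], dtype=np.intp)

    def __repr__(self):
        return f"{type(self).__name__}(n={len(self)})"


class GeneIndex(_IdIndex):
    """Canonical ordering of the N genes under study."""


class DiseaseIndex(_IdIndex):
    """Canonical ordering of the M diseases (phenotypes) under study."""


@dataclass
class KernelMatrix:
    """A labeled symmetric positive semidefinite similarity matrix.

    ``values[i, j]`` is the similarity between ``index.ids[i]`` and
    ``index.ids[j]``; over genes or over diseases depending on the index.
    """

    index: _IdIndex
    values: np.ndarray
    source_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match index size {n}"
            )
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix is asymmetric: max |K_ij - K_ji| = {asym:.3g}")

    # kernel-provider protocol shared with the lazy pairwise kernel
    @property
    def n_items(self) -> int:
        return len(self.index)

    @property
    def item_labels(self) -> tuple[str, ...]:
        return self.index.ids

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense sub-block ``K[rows][:, cols]``."""
        return self.values[np.ix_(rows, cols)]


@dataclass
class AssociationTable:
    """The training set of known (disease, gene) positive pairs."""

    pairs: tuple[tuple[str, str], ...]
    genes: GeneIndex
    diseases: DiseaseIndex
    positives: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self):
        self.pairs = tuple((str(d), str(g)) for d, g in self.pairs)
        seen = set()
        for d, g in self.pairs:
            if (d, g) in seen:
                raise ValueError(f"duplicate association ({d}, {g})")
            seen.add((d, g))
            if d not in self.diseases:
                raise KeyError(f"unknown disease {d!r} in associations")
            if g not in self.genes:
                raise KeyError(f"unknown gene {g!r} in associations")
        by_disease: dict[str, list[str]] = {}
        for d, g in self.pairs:
            by_disease.setdefault(d, []).append(g)
        self.positives = {d: tuple(gs) for d, gs in by_disease.items()}

    @property
    def T(self) -> int:
        """Total number of known disease-gene pairs."""
        return len(self.pairs)

    def positive_set(self, disease_id: str) -> frozenset[str]:
        return frozenset(self.positives.get(disease_id, ()))

    def without(self, disease_id: str, gene_id: str) -> "AssociationTable":
        """A copy with one association removed (leave-one-out helper)."""
        kept = tuple(p for p in self.pairs if p != (disease_id, gene_id))
        if len(kept) == self.T:
            raise KeyError(f"association ({disease_id}, {gene_id}) not present")
        return AssociationTable(kept, self.genes, self.diseases)


@dataclass
class RankingTable:
    """Per-disease candidate genes ordered by decreasing prioritization score."""

    disease_id: str
    gene_ids: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        if not (len(self.gene_ids) == len(self.scores) == len(self.ranks)):
            raise ValueError("gene_ids, scores and ranks must have equal length")
        if len(self.scores) and np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("rows must be sorted by decreasing score")
        if len(self.ranks) and self.ranks.min() < 1:
            raise ValueError("ranks must be >= 1")

    def __len__(self):
        return len(self.gene_ids)

    def rank_of(self, gene_id: str) -> float:
        i = self.gene_ids.index(gene_id)
        return float(self.ranks[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease_id": self.disease_id,
                "gene_id": self.gene_ids,
                "score": self.scores,
                "rank": self.ranks,
            }
        )


@dataclass
class RunConfig:
    """Settings shared by all prioritization entry points.

    Defaults follow the method's reference settings: ``B = 30`` bootstrap
    rounds and SVM cost ``C = 1``.  ``subsample_size="auto"`` draws as many
    unlabeled items per round as there are positives.
    """

    variant: int = 2
    B: int = 30
    C: float = 1.0
    subsample_size: int | str = "auto"
    seed: int = 0
    tie_rule: str = "mid"
    kernel_fusion: str = "mean"
    include_training: bool = False

    def __post_init__(self):
        if self.variant not in (1, 2, 3, 4):
            raise ValueError(f"variant must be in 1..4, got {self.variant}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.tie_rule not in ("mid", "worst"):
            raise ValueError("tie_rule must be 'mid' or 'worst'")
        if self.kernel_fusion != "mean":
            raise ValueError("only 'mean' kernel fusion is supported")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def read_square_matrix(path, kind: str = "gene") -> KernelMatrix:
    """Read a labeled square matrix (tab-delimited text or HDF5).

    The first row and first column must carry identical labels in identical
    order.  ``kind`` selects the index type ('gene' or 'disease').
    """
    path = Path(path)
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as f:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][...]]
            values = np.asarray(f["values"][...], dtype=float)
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except ValueError as e:
            raise FormatError(f"{path}: cannot parse matrix: {e}") from e
        if df.shape[0] != df.shape[1]:
            raise FormatError(
                f"{path}: matrix is not square ({df.shape[0]} rows, {df.shape[1]} columns)"
            )
        row_labels = [str(i) for i in df.index]
        col_labels = [str(c) for c in df.columns]
        if row_labels != col_labels:
            raise FormatError(
                f"{path}: row labels do not match column labels "
                f"(first mismatch near {next((a, b) for a, b in zip(row_labels, col_labels) if a != b)})"
            )
        bad = df.map(lambda v: isinstance(v, str))
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"{path}: non-numeric cell at row {row_labels[i]!r}, column {col_labels[j]!r}"
            )
        ids = row_labels
        values = df.to_numpy(dtype=float)
    index = GeneIndex(ids) if kind == "gene" else DiseaseIndex(ids)
    return KernelMatrix(index=index, values=values, source_name=path.stem)


def write_square_matrix(kernel: KernelMatrix, path) -> None:
    """Write a labeled square matrix in the dialect of :func:`read_square_matrix`."""
    path = Path(path)
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("ids", data=np.array(list(kernel.index.ids), dtype="S"))
            f.create_dataset("values", data=kernel.values)
        return
    df = pd.DataFrame(kernel.values, index=kernel.index.ids, columns=kernel.index.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path, kind: str = "gene"):
    """Read a genes x features table (tab-delimited; first column = gene id).

    Returns a :class:`~prodige.gene_kernels.FeatureTable` ready for
    :func:`~prodige.gene_kernels.linear_kernel`.
    """
    from .gene_kernels import FeatureTable

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: feature table needs at least one feature column")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric feature value: {e}") from e
    index = GeneIndex([str(i) for i in df.index])
    return FeatureTable(index=index, values=values, source_name=path.stem)


def read_edge_list(path, genes: GeneIndex | None = None):
    """Read an undirected interaction edge list (two or three tab columns).

    A third column, when present, holds positive edge weights.  With no
    explicit gene index, the index is built from the endpoint ids in order
    of first appearance.
    """
    from .gene_kernels import InteractionGraph

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty edge list")
    start = 0
    first = lines[0].split("\t")
    if genes is not None and (first[0] not in genes or first[1] not in genes):
        start = 1
    elif genes is None and len(first) >= 3:
        try:
            float(first[2])
        except ValueError:
            start = 1
    edges: list[tuple[str, str]] = []
    weights: list[float] = []
    seen_ids: list[str] = []
    seen_set: set[str] = set()
    for ln_no, ln in enumerate(lines[start:], start=start + 1):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{ln_no}: expected at least two columns")
        a, b = fields[0].strip(), fields[1].strip()
        edges.append((a, b))
        if len(fields) >= 3:
            weights.append(float(fields[2]))
        for x in (a, b):
            if x not in seen_set:
                seen_set.add(x)
                seen_ids.append(x)
    index = genes if genes is not None else GeneIndex(seen_ids)
    return InteractionGraph(
        index=index,
        edges=tuple(edges),
        weights=tuple(weights) if weights else None,
        source_name=path.stem,
    )


def read_associations(
    path,
    genes: GeneIndex,
    diseases: DiseaseIndex,
    strict: bool = True,
    header: bool | str = "auto",
) -> AssociationTable:
    """Read a two-column (disease_id, gene_id) association file.

    Duplicate pairs are dropped with a logged warning.  Unknown identifiers
    raise in strict mode and are dropped (with a warning) in lenient mode.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty association file")
    start = 0
    if header == "auto":
        first = lines[0].split("\t")
        if len(first) >= 2 and (first[0] not in diseases or first[1] not in genes):
            start = 1
    elif header:
        start = 1
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for ln_no, ln in enumerate(lines[start:], start=start + 1):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{ln_no}: expected two tab-separated columns")
        d, g = fields[0].strip(), fields[1].strip()
        if d not in diseases or g not in genes:
            msg = f"{path}:{ln_no}: unknown identifier in pair ({d!r}, {g!r})"
            if strict:
                raise KeyError(msg)
            logger.warning("%s -- dropped (lenient mode)", msg)
            continue
        if (d, g) in seen:
            n_dup += 1
            continue
        seen.add((d, g))
        pairs.append((d, g))
    if n_dup:
        logger.warning("%s: dropped %d duplicate association(s)", path, n_dup)
    if not pairs:
        raise FormatError(f"{path}: no usable associations")
    return AssociationTable(tuple(pairs), genes, diseases)


def write_associations(assoc: AssociationTable, path) -> None:
    with open(path, "w") as f:
        f.write("disease_id\tgene_id\n")
        for d, g in assoc.pairs:
            f.write(f"{d}\t{g}\n")


def write_ranking(table: RankingTable, path) -> None:
    """Write a ranking as a 4-column delimited file (header + one row per gene)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ranking(path) -> RankingTable:
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str, "gene_id": str})
    if df.empty:
        raise FormatError(f"{path}: ranking file has no rows")
    disease = df["disease_id"].iloc[0]
    return RankingTable(
        disease_id=str(disease),
        gene_ids=tuple(df["gene_id"].astype(str)),
        scores=df["score"].to_numpy(),
        ranks=df["rank"].to_numpy(),
    )
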