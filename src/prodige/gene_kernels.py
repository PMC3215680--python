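"""Build, normalize, validate and fuse gene kernels.

Each data source describing genes (expression profiles, annotation vectors,
an interaction graph, ...) is turned into a symmetric positive semidefinite
kernel over the common :class:`~prodige.data_model_io.GeneIndex`.  Sources
are made comparable by unit-diagonal normalization

    K'(G, G') = K(G, G') / sqrt(K(G, G) * K(G', G'))

and fused into a single kernel by entrywise averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .data_model_io import GeneIndex, KernelMatrix, PSD_REL_TOL, SYMMETRY_TOL

__all__ = [
    "FeatureTable",
    "InteractionGraph",
    "linear_kernel",
    "diffusion_kernel",
    "normalize_kernel",
    "mean_kernel",
    "check_psd",
    "fuse_kernels",
]


@dataclass
class FeatureTable:
    """A genes x features real matrix: one feature vector per gene."""

    index: GeneIndex
    values: np.ndarray
    source_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature table must be 2-dimensional")
        if self.values.shape[0] != len(self.index):
            raise ValueError(
                f"{self.values.shape[0]} feature rows for {len(self.index)} genes"
            )
        if self.values.shape[1] < 1:
            raise ValueError("feature table needs at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values in source {self.source_name!r}")


@dataclass
class InteractionGraph:
    """An undirected gene interaction graph over a GeneIndex.

    Edges are unordered pairs of gene identifiers; optional positive weights.
    """

    index: GeneIndex
    edges: tuple[tuple[str, str], ...]
    weights: tuple[float, ...] | None = None
    source_name: str = ""

    def __post_init__(self):
        norm = []
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if a not in self.index or b not in self.index:
                raise KeyError(f"edge endpoint not in gene index: ({a!r}, {b!r})")
            norm.append((a, b))
        self.edges = tuple(norm)
        if self.weights is not None:
            self.weights = tuple(float(w) for w in self.weights)
            if len(self.weights) != len(self.edges):
                raise ValueError("one weight per edge required")
            if any(w <= 0 for w in self.weights):
                raise ValueError("edge weights must be positive")

    def adjacency(self) -> np.ndarray:
        n = len(self.index)
        A = np.zeros((n, n))
        ws = self.weights or (1.0,) * len(self.edges)
        for (a, b), w in zip(self.edges, ws):
            i, j = self.index.position(a), self.index.position(b)
            A[i, j] += w
            A[j, i] += w
        return A

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.index.ids)
        ws = self.weights or (1.0,) * len(self.edges)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in zip(self.edges, ws))
        return g


def linear_kernel(features: FeatureTable) -> KernelMatrix:
    """Inner-product kernel K_ij = <phi(G_i), phi(G_j)> of a feature table."""
    X = features.values
    K = X @ X.T
    K = (K + K.T) / 2.0  # exact symmetry despite BLAS rounding
    return KernelMatrix(index=features.index, values=K, source_name=features.source_name)


def diffusion_kernel(graph: InteractionGraph, beta: float = 1.0) -> KernelMatrix:
    """Heat diffusion kernel exp(-beta * L) on an interaction graph.

    L is the combinatorial Laplacian D - A.  Computed by eigendecomposition
    of L, which guarantees a symmetric PSD result.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    A = graph.adjacency()
    L = np.diag(A.sum(axis=1)) - A
    w, V = scipy.linalg.eigh(L)
    K = (V * np.exp(-beta * w)) @ V.T
    K = (K + K.T) / 2.0
    return KernelMatrix(
        index=graph.index, values=K, source_name=graph.source_name or "diffusion"
    )


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Unit-diagonal normalization K_ij / sqrt(K_ii * K_jj).

    Errors if any diagonal entry is non-positive (the rescaling is undefined
    for a gene with zero self-similarity).  Idempotent and PSD-preserving.
    """
    d = np.diag(K.values)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive diagonal for {[K.index.ids[i] for i in bad[:5]]}; "
            "unit-diagonal normalization undefined"
        )
    s = 1.0 / np.sqrt(d)
    values = K.values * np.outer(s, s)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(index=K.index, values=values, source_name=K.source_name)


def mean_kernel(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Entrywise mean of L kernels sharing one index (kernel data fusion)."""
    if not kernels:
        raise ValueError("need at least one kernel to average")
    index = kernels[0].index
    for k in kernels[1:]:
        if k.index != index:
            raise ValueError(
                f"kernel {k.source_name!r} is indexed differently from "
                f"{kernels[0].source_name!r}"
            )
    values = np.mean([k.values for k in kernels], axis=0)
    name = "mean(" + ",".join(k.source_name or "?" for k in kernels) + ")"
    return KernelMatrix(index=index, values=values, source_name=name)


def fuse_kernels(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Normalize each source kernel to unit diagonal, then average.

    Normalizing first makes values comparable across heterogeneous sources;
    the mean of unit-diagonal kernels again has unit diagonal.
    """
    return mean_kernel([normalize_kernel(k) for k in kernels])


def check_psd(K: KernelMatrix, tol: float = PSD_REL_TOL) -> tuple[bool, float]:
    """Report the smallest eigenvalue of K and whether K is PSD within tolerance.

    ``ok`` iff min eigenvalue >= -tol * max(diag).  The input must already be
    symmetric (KernelMatrix enforces this on construction).
    """
    asym = np.max(np.abs(K.values - K.values.T))
    if asym > SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetric beyond tolerance: {asym:.3g}")
    w = scipy.linalg.eigvalsh(K.values)
    min_eig = float(w[0])
    scale = float(np.max(np.diag(K.values))) if len(K.index) else 1.0
    return min_eig >= -tol * max(scale, 1e-300), min_eig
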