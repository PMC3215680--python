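"""Positive-unlabeled learning by a bagging biased SVM on a precomputed kernel.

Given positives P and unlabeled items U, each bootstrap round draws a random
subsample U_b of U, trains a soft-margin SVM that discriminates P (label +1)
from U_b (label -1), and the rounds are aggregated into a single score per
unlabeled item.  An item's score is the mean decision value over the rounds
in which it was *not* drawn as a training negative (out-of-bag aggregation):
rounds in which an item served as a negative systematically depress its
decision value, so excluding them removes that bias.  Items never out of bag
fall back to the mean over all rounds.

The SVM has no intercept term.  Its dual is then a box-constrained quadratic
program

    min_a  (1/2) a' Q a - 1'a,   0 <= a_i <= C_i,   Q_ij = y_i y_j K_ij,

without the usual equality constraint sum(a_i y_i) = 0.  Dropping the
intercept is what makes the Dirac disease kernel decompose the multi-disease
pair problem exactly into independent per-disease problems: with a
block-diagonal Gram there is no constraint coupling the blocks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import scipy.optimize

__all__ = [
    "PUProblem",
    "PUScores",
    "BiasedSVM",
    "BaggedPUModel",
    "fit_biased_svm",
    "fit_pu_model",
    "fit_pu_scores",
    "decision_values",
]


class KernelProvider(Protocol):
    """Anything that can serve dense sub-blocks of a (possibly huge) kernel."""

    @property
    def n_items(self) -> int: ...

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray: ...


@dataclass
class PUProblem:
    """A kernel plus disjoint index sets of positive and unlabeled items.

    ``labels`` optionally names each kernel item; the bootstrap subsampling
    is keyed on these identities (falling back to the kernel's own item
    labels, then to stringified indices), so results do not depend on the
    storage order of the inputs.
    """

    kernel: KernelProvider
    positives: np.ndarray
    unlabeled: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self):
        self.positives = np.asarray(self.positives, dtype=np.intp)
        self.unlabeled = np.asarray(self.unlabeled, dtype=np.intp)
        if self.labels is None:
            self.labels = getattr(self.kernel, "item_labels", None)
        if self.labels is not None and len(self.labels) != self.kernel.n_items:
            raise ValueError("need one label per kernel item")
        if self.positives.size < 1:
            raise ValueError("PU learning requires known positive examples")
        if self.unlabeled.size < 1:
            raise ValueError("no unlabeled items to score")
        n = self.kernel.n_items
        for name, idx in (("positive", self.positives), ("unlabeled", self.unlabeled)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise IndexError(f"{name} index out of kernel bounds (n={n})")
        if len(set(self.positives.tolist())) != self.positives.size:
            raise ValueError("duplicate positive indices")
        if set(self.positives.tolist()) & set(self.unlabeled.tolist()):
            raise ValueError("positive and unlabeled sets must be disjoint")


@dataclass
class PUScores:
    """Aggregated confidence scores for the unlabeled items of a PUProblem."""

    items: np.ndarray  # kernel indices, same order as scores
    scores: np.ndarray  # higher = more confidently positive
    coverage: np.ndarray  # number of out-of-bag rounds per item
    B: int
    subsample_size: int
    seed: int

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(s) for i, s in zip(self.items, self.scores)}


def _solve_box_qp(Q: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Minimize (1/2) a'Qa - 1'a subject to 0 <= a <= upper.

    Q is symmetric PSD (a label-signed Gram matrix), so the problem is
    convex and smooth; L-BFGS-B with an analytic gradient converges to high
    accuracy.  The result is clipped back into the box.
    """
    n = Q.shape[0]

    def fun_grad(a):
        Qa = Q @ a
        return 0.5 * float(a @ Qa) - float(a.sum()), Qa - 1.0

    x0 = np.minimum(upper, 0.5 * np.min(upper))
    res = scipy.optimize.minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, float(u)) for u in upper],
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return np.clip(res.x, 0.0, upper)


@dataclass
class BiasedSVM:
    """One fitted no-intercept SVM in the kernel dual representation."""

    train_items: np.ndarray  # kernel indices of training items
    y: np.ndarray  # +1 for positives, -1 for (sub)sampled unlabeled
    alpha: np.ndarray  # dual coefficients, 0 <= alpha_i <= C_i

    @property
    def coef(self) -> np.ndarray:
        """alpha_i * y_i, the expansion weights of the decision function."""
        return self.alpha * self.y

    def decision_values(self, kernel_rows: np.ndarray) -> np.ndarray:
        return decision_values(self, kernel_rows)


def decision_values(model: BiasedSVM, kernel_rows: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x, x_i) for each query row.

    ``kernel_rows`` must have one column per training item, in the order of
    ``model.train_items``.
    """
    kernel_rows = np.atleast_2d(np.asarray(kernel_rows, dtype=float))
    if kernel_rows.shape[1] != model.train_items.size:
        raise ValueError(
            f"kernel rows have {kernel_rows.shape[1]} columns for "
            f"{model.train_items.size} training items"
        )
    return kernel_rows @ model.coef


def fit_biased_svm(
    kernel: KernelProvider,
    positives: np.ndarray,
    negatives: np.ndarray,
    C: float = 1.0,
    positive_weight: float = 1.0,
) -> BiasedSVM:
    """Train one soft-margin SVM with labels +1 on P and -1 on the given negatives.

    ``positive_weight`` multiplies the cost C on the positive class, for the
    classical (non-bagged) biased-SVM mode; the bagging engine leaves it at 1
    and realizes the bias toward positives by subsampling the unlabeled set.
    """
    positives = np.asarray(positives, dtype=np.intp)
    negatives = np.asarray(negatives, dtype=np.intp)
    train = np.concatenate([positives, negatives])
    y = np.concatenate([np.ones(positives.size), -np.ones(negatives.size)])
    G = kernel.block(train, train)
    G = (G + G.T) / 2.0
    Q = (y[:, None] * y[None, :]) * G
    upper = np.where(y > 0, C * positive_weight, C)
    alpha = _solve_box_qp(Q, upper)
    return BiasedSVM(train_items=train, y=y, alpha=alpha)


@dataclass
class BaggedPUModel:
    """The B fitted rounds of a bagging biased SVM plus their in-bag records."""

    models: list[BiasedSVM]
    in_bag: list[frozenset[int]]  # kernel indices drawn as negatives per round
    kernel: KernelProvider
    seed: int
    subsample_size: int

    @property
    def B(self) -> int:
        return len(self.models)

    def score_items(self, items: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-bag aggregated scores (and coverage counts) for given items."""
        items = np.asarray(items, dtype=np.intp)
        total_oob = np.zeros(items.size)
        total_all = np.zeros(items.size)
        coverage = np.zeros(items.size, dtype=int)
        for model, bag in zip(self.models, self.in_bag):
            dv = decision_values(model, self.kernel.block(items, model.train_items))
            oob = np.fromiter((i not in bag for i in items.tolist()), bool, items.size)
            total_all += dv
            total_oob[oob] += dv[oob]
            coverage += oob
        scores = np.where(
            coverage > 0, total_oob / np.maximum(coverage, 1), total_all / self.B
        )
        return scores, coverage


def _label_hash(label: str) -> np.uint64:
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    return np.frombuffer(digest, dtype=np.uint64)[0]


def _mix(base: np.ndarray, round_key: np.uint64) -> np.ndarray:
    """splitmix64 finalizer: decorrelates per-item hashes across rounds."""
    with np.errstate(over="ignore"):
        z = (base ^ round_key) + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _round_subsample(
    unlabeled: np.ndarray, base_keys: np.ndarray, size: int, seed: int,
    round_index: int,
) -> np.ndarray:
    """The unlabeled subsample for one bootstrap round.

    Each item carries a stable hash of its identity; mixing it with a key
    derived from (seed, round index) yields a per-round priority, and the
    ``size`` smallest priorities are drawn.  Hence the draw is a uniform
    subsample that is invariant to storage order, and earlier rounds are
    unchanged when B grows.
    """
    round_key = _label_hash(f"{seed}|{round_index}")
    priority = _mix(base_keys, round_key)
    order = np.argsort(priority, kind="stable")
    return unlabeled[order[:size]]


def fit_pu_model(
    problem: PUProblem,
    B: int = 30,
    subsample_size: int | str = "auto",
    C: float = 1.0,
    seed: int = 0,
) -> BaggedPUModel:
    """Fit the B bootstrap rounds of the bagging biased SVM.

    Each round draws a uniform subsample of the unlabeled set (default size
    |P|, giving balanced base classifiers) and trains P against it with equal
    cost C on both classes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if subsample_size == "auto":
        size = min(problem.positives.size, problem.unlabeled.size)
    else:
        size = int(subsample_size)
    if size < 1 or size > problem.unlabeled.size:
        raise ValueError(
            f"subsample size {size} out of range for |U| = {problem.unlabeled.size}"
        )
    if problem.labels is not None:
        u_labels = [str(problem.labels[i]) for i in problem.unlabeled]
    else:
        u_labels = [str(int(i)) for i in problem.unlabeled]
    base_keys = np.array([_label_hash(l) for l in u_labels], dtype=np.uint64)
    models: list[BiasedSVM] = []
    in_bag: list[frozenset[int]] = []
    for b in range(B):
        u_b = _round_subsample(problem.unlabeled, base_keys, size, seed, b)
        models.append(fit_biased_svm(problem.kernel, problem.positives, u_b, C=C))
        in_bag.append(frozenset(u_b.tolist()))
    return BaggedPUModel(
        models=models,
        in_bag=in_bag,
        kernel=problem.kernel,
        seed=seed,
        subsample_size=size,
    )


def fit_pu_scores(
    problem: PUProblem,
    B: int = 30,
    subsample_size: int | str = "auto",
    C: float = 1.0,
    seed: int = 0,
) -> PUScores:
    """Bagging biased SVM scores for every unlabeled item of a PU problem."""
    model = fit_pu_model(problem, B=B, subsample_size=subsample_size, C=C, seed=seed)
    scores, coverage = model.score_items(problem.unlabeled)
    return PUScores(
        items=problem.unlabeled.copy(),
        scores=scores,
        coverage=coverage,
        B=model.B,
        subsample_size=model.subsample_size,
        seed=seed,
    )
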