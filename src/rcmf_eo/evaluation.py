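"""Fitness function and evaluation metrics for the wrapper stage.

The fitness of a gene subset s over a candidate space of size N is

    Fitness(s) = alpha * E(s) + (1 - alpha) * R / N

where E(s) is the pooled misclassification error of a K-nearest-neighbor
classifier under stratified cross-validation and R = |s|.  With the
default alpha = 0.9 the error term dominates and the size term breaks
ties toward smaller subsets, which is what drives the pruning strategy.

The CV partition is fixed once per run (``fold_seed``), so fitness is a
deterministic, memoizable function of the subset — a prerequisite for a
monotone convergence trace.

Also provided: Jaccard selection stability, G-mean, hard-prediction
AUC/MAUC, and replicate summaries (MeanA / MeanS / MeanF with std).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FitnessSpec",
    "KnnCvFitness",
    "RunResult",
    "jaccard_stability",
    "g_mean",
    "auc_mauc",
    "summarize_replicates",
]


@dataclass(frozen=True)
class FitnessSpec:
    """Parameters of the subset-fitness evaluation."""

    n_candidates: int
    alpha: float = 0.9
    knn_k: int = 5
    cv_folds: int = 10
    fold_seed: int = 0
    standardize: str = "zscore"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


class KnnCvFitness:
    """Memoized KNN cross-validation fitness over a fixed candidate matrix.

    ``values`` holds the candidate gene columns (samples x D).  Folds are
    stratified and pinned by ``spec.fold_seed``; per-fold z-scoring uses
    training-fold statistics only.  KNN ties are deterministic: equal
    distances prefer the smaller training index, vote ties the smallest
    class code.
    """

    def __init__(self, values: np.ndarray, labels: Sequence[int], spec: FitnessSpec):
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        if values.ndim != 2 or values.shape[0] != labels.shape[0]:
            raise ValueError("values must be samples x genes matching labels")
        self.spec = spec
        self.n_samples, self.n_genes = values.shape
        self.n_classes = int(labels.max()) + 1
        skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                              random_state=spec.fold_seed)
        self._folds = []
        for train_idx, test_idx in skf.split(values, labels):
            train_idx = np.sort(train_idx)
            test_idx = np.sort(test_idx)
            tr, te = values[train_idx], values[test_idx]
            if spec.standardize == "zscore":
                mu = tr.mean(axis=0)
                sd = tr.std(axis=0)
                sd[sd == 0] = 1.0
                tr = (tr - mu) / sd
                te = (te - mu) / sd
            self._folds.append((tr, labels[train_idx], te, labels[test_idx]))
        self._memo: dict[bytes, float] = {}
        self.n_evaluations = 0

    def _key(self, subset: np.ndarray) -> bytes:
        return subset.tobytes()

    def error(self, subset: Sequence[int]) -> float:
        """Pooled CV misclassification error of the subset."""
        subset = np.unique(np.asarray(subset, dtype=np.int64))
        if subset.size == 0:
            raise ValueError("subset is empty")
        if subset.min() < 0 or subset.max() >= self.n_genes:
            raise ValueError("subset index out of range")
        key = self._key(subset)
        if key in self._memo:
            return self._memo[key]
        k = self.spec.knn_k
        wrong = 0
        for tr, ytr, te, yte in self._folds:
            d = _sqdist(te[:, subset], tr[:, subset])
            order = np.argsort(d, axis=1, kind="stable")[:, :k]
            neigh = ytr[order]
            votes = np.zeros((te.shape[0], self.n_classes), dtype=np.int64)
            np.add.at(votes, (np.repeat(np.arange(te.shape[0]), neigh.shape[1]),
                              neigh.ravel()), 1)
            pred = votes.argmax(axis=1)  # vote tie -> smallest class code
            wrong += int((pred != yte).sum())
        err = wrong / self.n_samples
        self._memo[key] = err
        self.n_evaluations += 1
        return err

    def fitness(self, subset: Sequence[int]) -> float:
        subset = np.unique(np.asarray(subset, dtype=np.int64))
        err = self.error(subset)
        r = subset.size
        return self.spec.alpha * err + (1.0 - self.spec.alpha) * r / self.spec.n_candidates

    def accuracy(self, subset: Sequence[int]) -> float:
        return 1.0 - self.error(subset)


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between the rows of a and of b."""
    sq_a = (a ** 2).sum(axis=1)[:, None]
    sq_b = (b ** 2).sum(axis=1)[None, :]
    d = sq_a + sq_b - 2.0 * (a @ b.T)
    return np.maximum(d, 0.0)


@dataclass
class RunResult:
    """Outcome of one (or several replicated) wrapper runs.

    ``best_subset`` is expressed in original gene indices.  ``replicates``
    holds one ``(accuracy, subset_size, fitness)`` tuple per independent
    run; ``summary`` the MeanA/MeanS/MeanF means and sample stds.
    """

    best_subset: list[int]
    best_fitness: float
    trace: list[float]
    replicates: list[tuple[float, int, float]] = field(default_factory=list)
    summary: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    variant: str = "gbgpseo"


def jaccard_stability(subsets: Sequence[Iterable[int]]) -> float:
    """Mean pairwise Jaccard index of Q gene sets (Q >= 2), in [0, 1].

    A pair of two empty sets contributes 1 (identically empty selections
    are perfectly stable).
    """
    sets = [set(s) for s in subsets]
    q = len(sets)
    if q < 2:
        raise ValueError("need at least two subsets")
    total = 0.0
    for i in range(q - 1):
        for j in range(i + 1, q):
            union = sets[i] | sets[j]
            total += 1.0 if not union else len(sets[i] & sets[j]) / len(union)
    return 2.0 * total / (q * (q - 1))


def _per_class_recall(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    recalls = np.empty(k)
    for c in range(k):
        mask = y_true == c
        if not mask.any():
            raise ValueError(f"class {c} absent from y_true")
        recalls[c] = (y_pred[mask] == c).mean()
    return recalls


def g_mean(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int | None = None) -> float:
    """Geometric mean of per-class recalls (binary: sqrt(sens * spec))."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    k = n_classes or int(y_true.max()) + 1
    recalls = _per_class_recall(y_true, y_pred, k)
    if (recalls == 0).any():
        return 0.0
    return float(np.exp(np.log(recalls).mean()))


def auc_mauc(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int | None = None) -> float:
    """Hard-prediction AUC: binary (1 + TPrate - FPrate) / 2; multi-class
    the unweighted mean of the one-vs-rest per-class AUCs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    k = n_classes or int(y_true.max()) + 1
    if k == 2:
        return _binary_auc(y_true, y_pred, positive=1)
    return float(np.mean([_binary_auc(y_true == c, y_pred == c, positive=True)
                          for c in range(k)]))


def _binary_auc(y_true, y_pred, positive) -> float:
    pos = y_true == positive
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both classes present")
    tp_rate = (y_pred[pos] == positive).mean()
    fp_rate = (y_pred[neg] == positive).mean()
    return float((1.0 + tp_rate - fp_rate) / 2.0)


def summarize_replicates(replicates: Sequence[tuple[float, int, float]]) -> dict[str, float]:
    """MeanA/MeanS/MeanF and sample standard deviations over replicates.

    A single replicate reports std 0 by convention.
    """
    if not replicates:
        raise ValueError("no replicates to summarize")
    arr = np.asarray(replicates, dtype=float)
    means = arr.mean(axis=0)
    stds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(3)
    return {
        "MeanA": float(means[0]), "StdA": float(stds[0]),
        "MeanS": float(means[1]), "StdS": float(stds[1]),
        "MeanF": float(means[2]), "StdF": float(stds[2]),
    }
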