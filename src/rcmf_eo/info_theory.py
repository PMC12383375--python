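"""Plug-in information measures on discretized expression values.

All measures (entropy, information gain, symmetric uncertainty, mutual
information, conditional mutual information, mRMR) operate on discrete
codes obtained from one shared equal-frequency discretization, so that
every stage-1 decision is made on the same view of the data.  Logarithms
are base 2 throughout: every quantity is in bits.

Probabilities are plug-in (maximum-likelihood) estimates of the joint
contingency table, with no smoothing.  Under plug-in estimation the
conditional mutual information is non-negative by construction; tiny
negative values produced by floating-point cancellation are clipped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiscretizedView",
    "discretize",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "symmetric_uncertainty",
    "mutual_information",
    "conditional_mutual_information",
    "mrmr_rank",
]


@dataclass(frozen=True)
class DiscretizedView:
    """Integer bin codes for a samples x genes expression matrix.

    ``codes[s, g]`` is the equal-frequency bin of sample ``s`` for gene
    ``g``, in ``[0, n_bins)``.  ``boundaries[g]`` holds the ``n_bins - 1``
    interior bin edges of gene ``g``; values equal to an edge fall in the
    lower bin.
    """

    codes: np.ndarray
    n_bins: int
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D samples x genes array")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.n_bins):
            raise ValueError("codes out of range [0, n_bins)")

    @property
    def n_genes(self) -> int:
        return self.codes.shape[1]


def discretize(values: np.ndarray, n_bins: int = 5) -> DiscretizedView:
    """Equal-frequency binning of each gene column into ``n_bins`` bins.

    Boundaries are the interior quantiles of each column; ties with a
    boundary are assigned to the lower bin.  Heavily tied columns may
    occupy fewer than ``n_bins`` distinct codes (duplicate boundaries
    collapse bins), which is the intended plug-in behaviour.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.arange(1, n_bins) / n_bins
    boundaries = np.quantile(values, qs, axis=0).T  # (genes, n_bins-1)
    codes = np.empty(values.shape, dtype=np.int64)
    for g in range(values.shape[1]):
        # side='left': a value equal to an edge gets the edge's own index,
        # i.e. the lower bin.
        codes[:, g] = np.searchsorted(boundaries[g], values[:, g], side="left")
    return DiscretizedView(codes=codes, n_bins=n_bins, boundaries=boundaries)


def _joint_codes(*variables: Sequence) -> np.ndarray:
    """Encode the tuple of discrete variables as a single integer code."""
    cols = [np.asarray(v).reshape(-1) for v in variables]
    n = cols[0].shape[0]
    if any(c.shape[0] != n for c in cols):
        raise ValueError("variables must have equal length")
    stacked = np.stack(cols, axis=1)
    _, inverse = np.unique(stacked, axis=0, return_inverse=True)
    return inverse


def entropy(x: Sequence) -> float:
    """Shannon entropy H(X) = -sum p(x) log2 p(x) in bits, with 0*log0 := 0."""
    x = np.asarray(x).reshape(-1)
    if x.size == 0:
        raise ValueError("entropy of an empty variable is undefined")
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(*variables: Sequence) -> float:
    return entropy(_joint_codes(*variables))


def conditional_entropy(x: Sequence, y: Sequence) -> float:
    """H(X|Y) = H(X,Y) - H(Y)."""
    return _joint_entropy(x, y) - entropy(y)


def information_gain(x: Sequence, y: Sequence) -> float:
    """IG(X, Y) = H(X) - H(X|Y); symmetric in its arguments."""
    return entropy(x) - conditional_entropy(x, y)


def mutual_information(x: Sequence, y: Sequence) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), clipped to be non-negative."""
    value = entropy(x) + entropy(y) - _joint_entropy(x, y)
    return max(value, 0.0)


def symmetric_uncertainty(x: Sequence, y: Sequence) -> float:
    """SU(X,Y) = 2*IG / (H(X) + H(Y)), in [0, 1].

    Convention: if both variables are constant (H(X) = H(Y) = 0) the
    association is undefined and SU is reported as 0.
    """
    hx, hy = entropy(x), entropy(y)
    if hx == 0.0 and hy == 0.0:
        return 0.0
    su = 2.0 * mutual_information(x, y) / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


def conditional_mutual_information(x: Sequence, y: Sequence, z: Sequence) -> float:
    """CMI(X;Y|Z) = H(X|Z) - H(X|Y,Z), clipped to be non-negative.

    The plug-in estimate is mathematically >= 0; clipping only removes
    floating-point cancellation noise.
    """
    value = (
        _joint_entropy(x, z)
        - entropy(z)
        - _joint_entropy(x, y, z)
        + _joint_entropy(y, z)
    )
    return max(value, 0.0)


def mrmr_rank(
    candidates: Sequence[int],
    codes: np.ndarray | DiscretizedView,
    labels: Sequence,
) -> list[int]:
    """Greedy minimum-redundancy maximum-relevance ordering of ``candidates``.

    The first gene maximizes relevance I(g; C); every subsequent gene
    maximizes I(g; C) - mean over already selected s of I(g; s).  Ties
    break toward the smaller gene index.  Returns the full ordering from
    most to least important.
    """
    if isinstance(codes, DiscretizedView):
        codes = codes.codes
    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("candidates must be nonempty")
    labels = np.asarray(labels).reshape(-1)
    relevance = {g: mutual_information(codes[:, g], labels) for g in candidates}
    remaining = sorted(candidates)
    selected: list[int] = []
    pair_mi: dict[tuple[int, int], float] = {}

    def redundancy(g: int) -> float:
        if not selected:
            return 0.0
        total = 0.0
        for s in selected:
            key = (min(g, s), max(g, s))
            if key not in pair_mi:
                pair_mi[key] = mutual_information(codes[:, g], codes[:, s])
            total += pair_mi[key]
        return total / len(selected)

    while remaining:
        # max score, ties by ascending gene index (remaining is sorted)
        best = max(remaining, key=lambda g: (relevance[g] - redundancy(g), -g))
        selected.append(best)
        remaining.remove(best)
    return selected
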