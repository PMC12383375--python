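"""Five univariate gene-relevance filters feeding the stage-1 ensemble.

Fisher score, ReliefF, chi-square, absolute Pearson correlation and
diagonal Neighborhood Component Analysis each score every gene against
the class label (higher = more relevant) and induce a top-N index list
with ties broken toward the smaller gene index.

Filters score raw expression values; scaling is applied only where a
distance is involved (ReliefF min-max scales to [0, 1], NCA z-scores),
so that each filter matches its textbook definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import LabeledDataset
from .info_theory import discretize

__all__ = [
    "GeneRanking",
    "top_n",
    "fisher_score",
    "relieff",
    "chi_square",
    "pearson",
    "nca_weights",
    "FILTERS",
]


@dataclass(frozen=True)
class GeneRanking:
    filter_name: str
    scores: np.ndarray
    top_n: tuple[int, ...]

    def __post_init__(self) -> None:
        if np.isnan(self.scores).any():
            raise ValueError("filter scores contain NaN")


def top_n(scores: np.ndarray, n: int) -> list[int]:
    """Indices of the ``n`` largest scores; ties broken by ascending index.

    +inf sorts above all finite scores; among equal scores (including
    several +inf) the smaller gene index wins.
    """
    scores = np.asarray(scores, dtype=float)
    if n > scores.shape[0]:
        raise ValueError("N exceeds the gene count")
    # lexsort: primary key -scores (descending score), secondary ascending index
    order = np.lexsort((np.arange(scores.shape[0]), -scores))
    return [int(i) for i in order[:n]]


def _ranking(name: str, scores: np.ndarray, n: int | None) -> GeneRanking:
    n = scores.shape[0] if n is None else n
    return GeneRanking(filter_name=name, scores=scores, top_n=tuple(top_n(scores, n)))


def fisher_score(data: LabeledDataset, n: int | None = None) -> GeneRanking:
    """Fisher score sum_k n_k (mu_gk - mu_g)^2 / sum_k n_k var_gk.

    Within-class variance is the population (divide-by-n_k) variance.
    A gene with zero pooled within-class variance but distinct class
    means scores +inf (ranked first); a fully constant gene scores 0.
    """
    if data.n_classes < 2:
        raise ValueError("Fisher score requires >= 2 classes")
    X, y = data.values, data.labels
    overall = X.mean(axis=0)
    num = np.zeros(data.n_genes)
    den = np.zeros(data.n_genes)
    for c in range(data.n_classes):
        Xc = X[y == c]
        nk = Xc.shape[0]
        mu = Xc.mean(axis=0)
        num += nk * (mu - overall) ** 2
        den += nk * Xc.var(axis=0)  # population variance
    scores = np.zeros(data.n_genes)
    pos = den > 0
    scores[pos] = num[pos] / den[pos]
    scores[(~pos) & (num > 0)] = np.inf
    return _ranking("fisher", scores, n)


def relieff(
    data: LabeledDataset,
    k_neighbors: int = 10,
    n_probes: int | None = None,
    rng_seed: int = 0,
    n: int | None = None,
) -> GeneRanking:
    """Multi-class ReliefF weights.

    Features are min-max scaled to [0, 1]; neighbor search uses the
    Manhattan distance on the scaled values.  For each probe sample the
    weight of every feature is decreased by its mean difference to the k
    nearest hits and increased by the class-prior-weighted mean
    difference to the k nearest misses of each other class.  With
    ``n_probes=None`` (default) every sample is a probe and the result
    is deterministic; a subsample of probes is drawn with ``rng_seed``.
    """
    X, y = data.values, data.labels
    n_samples, n_genes = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() <= k_neighbors:
        raise ValueError("every class must have more than k_neighbors samples")
    priors = counts / n_samples

    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span

    if n_probes is None or n_probes >= n_samples:
        probes = np.arange(n_samples)
    else:
        probes = np.sort(np.random.default_rng(rng_seed).choice(
            n_samples, size=n_probes, replace=False))

    dist = cdist(Z[probes], Z, metric="cityblock")
    W = np.zeros(n_genes)
    for row, i in enumerate(probes):
        yc = y[i]
        for c in classes:
            members = np.flatnonzero(y == c)
            if c == yc:
                members = members[members != i]
            # stable sort: distance ties resolve toward the smaller index
            order = members[np.argsort(dist[row, members], kind="stable")]
            nearest = order[:k_neighbors]
            mean_diff = np.abs(Z[i] - Z[nearest]).mean(axis=0)
            if c == yc:
                W -= mean_diff
            else:
                W += priors[c] / (1.0 - priors[yc]) * mean_diff
    W /= len(probes)
    return _ranking("relieff", W, n)


def chi_square(data: LabeledDataset, n_bins: int = 5, n: int | None = None) -> GeneRanking:
    """Chi-square statistic of the class x bin contingency table per gene.

    Genes are discretized with the shared equal-frequency binning;
    X^2 = sum (N_ij - E_ij)^2 / E_ij with E_ij = M_j * n_i / N; cells
    with zero expected count contribute 0.
    """
    codes = discretize(data.values, n_bins=n_bins).codes
    y = data.labels
    k = data.n_classes
    n_samples = data.n_samples
    class_counts = np.bincount(y, minlength=k).astype(float)
    scores = np.zeros(data.n_genes)
    for g in range(data.n_genes):
        obs = np.zeros((k, n_bins))
        np.add.at(obs, (y, codes[:, g]), 1.0)
        bin_counts = obs.sum(axis=0)
        expected = np.outer(class_counts, bin_counts) / n_samples
        mask = expected > 0
        scores[g] = (((obs - expected) ** 2)[mask] / expected[mask]).sum()
    return _ranking("chi2", scores, n)


def pearson(data: LabeledDataset, n: int | None = None) -> GeneRanking:
    """Absolute Pearson correlation |rho(gene, integer class code)|.

    A constant gene (or constant label, excluded by the dataset
    invariants) scores 0; both signs of correlation count as relevance.
    """
    X = data.values
    y = data.labels.astype(float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    den = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    scores = np.zeros(data.n_genes)
    ok = den > 0
    scores[ok] = np.abs(num[ok] / den[ok])
    return _ranking("pcc", np.clip(scores, 0.0, 1.0), n)


def _nca_objective_grad(Z, y, w, reg, chunk=128, want_grad=True):
    """Leave-one-out soft-neighbor objective and gradient for diagonal NCA.

    d_ij = sum_g w_g^2 (z_ig - z_jg)^2; p_ij = softmax_j(-d_ij) over j != i;
    objective = mean_i sum_{j in class(i)} p_ij - reg * ||w||^2.
    """
    n, G = Z.shape
    Zw = Z * w
    sq = (Zw ** 2).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (Zw @ Zw.T)
    np.fill_diagonal(d, np.inf)
    d -= d.min(axis=1, keepdims=True)  # softmax stabilization
    P = np.exp(-d)
    P /= P.sum(axis=1, keepdims=True)
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
    p_i = (P * same).sum(axis=1)
    obj = p_i.mean() - reg * float(w @ w)
    if not want_grad:
        return obj, None
    grad = np.zeros(G)
    W1 = (p_i[:, None] * P)          # weight of Delta in sum_i p_i sum_j p_ij Delta
    W2 = P * same                    # weight of Delta in sum_i sum_{j in class} p_ij Delta
    for start in range(0, G, chunk):
        cs = slice(start, min(start + chunk, G))
        Delta = (Z[:, None, cs] - Z[None, :, cs]) ** 2
        grad[cs] = np.einsum("ij,ijg->g", W1 - W2, Delta)
    grad = (2.0 * w / n) * grad - 2.0 * reg * w
    return obj, grad


def nca_weights(
    data: LabeledDataset,
    reg_lambda: float = 0.01,
    max_opt_iter: int = 50,
    rng_seed: int = 0,
    tol: float = 1e-8,
    n: int | None = None,
) -> GeneRanking:
    """Diagonal NCA feature weights by gradient ascent with backtracking.

    One weight per gene is learned from an all-ones start by maximizing
    the expected leave-one-out soft-neighbor classification objective
    with an L2 penalty ``reg_lambda``.  Distances are computed on
    z-scored expression.  The returned score is the squared weight (the
    effective per-gene metric scale), which is nonnegative.  The run is
    deterministic; ``rng_seed`` is accepted for interface symmetry.
    """
    del rng_seed  # deterministic: fixed initialization, no sampling
    X, y = data.values, data.labels
    if data.n_classes < 2:
        raise ValueError("NCA requires >= 2 classes")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    w = np.ones(data.n_genes)
    obj, grad = _nca_objective_grad(Z, y, w, reg_lambda)
    step = 1.0
    converged = False
    for _ in range(max_opt_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            converged = True
            break
        accepted = False
        for _ in range(30):  # backtracking: accept only non-decreasing objective
            w_new = w + step * grad
            obj_new, _ = _nca_objective_grad(Z, y, w_new, reg_lambda, want_grad=False)
            if obj_new >= obj - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if abs(obj_new - obj) < tol:
            w = w_new
            obj = obj_new
            converged = True
            break
        w = w_new
        obj, grad = _nca_objective_grad(Z, y, w, reg_lambda)
        step *= 1.2
    else:
        converged = False
    if not converged and max_opt_iter > 0:
        import warnings

        warnings.warn("NCA did not converge; returning the last iterate", RuntimeWarning)
    return _ranking("nca", w ** 2, n)


#: name -> callable(data, n=...) with per-filter defaults applied by the caller
FILTERS = {
    "fisher": fisher_score,
    "relieff": relieff,
    "chi2": chi_square,
    "pcc": pearson,
    "nca": nca_weights,
}
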