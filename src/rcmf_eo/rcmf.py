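"""Stage 1: the redundancy-and-complementarity multi-filter ensemble.

Five filters each nominate their top-N genes.  The union F of the five
lists is pruned with an approximate-Markov-blanket test on symmetric
uncertainty (a gene is redundant when an earlier-kept gene is at least
as class-relevant and at least as associated with it as it is with the
class).  Genes nominated by *all five* filters form the consensus set P;
the consensus genes surviving the redundancy pass are the "strong"
output.  The remaining survivors are then screened for complementarity:
a gene is retained when conditioning on some strong gene increases its
information about the class (interaction gain of the conditional over
the marginal mutual information).  The candidate set handed to the
wrapper is strong ∪ complementary.

The redundancy pass walks F in its listed order, exactly as the
pseudocode's double loop does; consensus genes receive no special
protection and can blanket one another.  An alternative
``order="relevance"`` processes genes in descending class-SU (FCBF
style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import LabeledDataset, RunConfig
from .filters import GeneRanking, chi_square, fisher_score, nca_weights, pearson, relieff
from .info_theory import (
    DiscretizedView,
    conditional_mutual_information,
    discretize,
    mutual_information,
    symmetric_uncertainty,
)

__all__ = ["CandidateSet", "build_filter_sets", "redundancy_prune",
           "complementarity_select", "run_rcmf"]


@dataclass
class CandidateSet:
    """Stage-1 output: the candidate gene universe for the wrapper.

    ``strong`` — consensus genes (selected by all five filters) that
    survive redundancy pruning; ``complementary`` — genes retained by the
    CMI interaction test; ``removed_redundant`` — genes eliminated by the
    Markov-blanket pass; ``final`` — ordered union strong ∪ complementary.
    """

    strong: list[int]
    complementary: list[int]
    removed_redundant: list[int]
    final: list[int]
    rankings: dict[str, GeneRanking] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if set(self.strong) & set(self.complementary):
            raise ValueError("strong and complementary must be disjoint")
        if set(self.removed_redundant) & set(self.final):
            raise ValueError("removed genes cannot appear in the final set")
        if set(self.final) != set(self.strong) | set(self.complementary):
            raise ValueError("final must equal strong ∪ complementary")

    def provenance(self, gene: int) -> str:
        if gene in self.strong:
            return "strong"
        if gene in self.complementary:
            return "complementary"
        raise KeyError(gene)


def build_filter_sets(
    data: LabeledDataset, n: int, cfg: RunConfig | None = None
) -> tuple[list[int], list[int], dict[str, GeneRanking]]:
    """Run the five filters at top-N = ``n``.

    Returns ``(F, P, rankings)`` with F the union and P the intersection
    of the five top-N lists, both in ascending gene-index order.
    """
    cfg = cfg or RunConfig()
    if n > data.n_genes:
        raise ValueError("top-N exceeds the gene count")
    rankings = {
        "fisher": fisher_score(data, n=n),
        "relieff": relieff(data, k_neighbors=cfg.relieff_k, n=n),
        "chi2": chi_square(data, n_bins=cfg.n_bins, n=n),
        "pcc": pearson(data, n=n),
        "nca": nca_weights(data, reg_lambda=cfg.nca_reg,
                           max_opt_iter=cfg.nca_max_iter, n=n),
    }
    tops = [set(r.top_n) for r in rankings.values()]
    F = sorted(set.union(*tops))
    P = sorted(set.intersection(*tops))
    return F, P, rankings


def redundancy_prune(
    F: Sequence[int],
    view: DiscretizedView | np.ndarray,
    labels: Sequence[int],
    order: str = "input",
    protected: Sequence[int] = (),
) -> tuple[list[int], list[int]]:
    """Single-pass approximate-Markov-blanket redundancy removal.

    A gene ``fj`` is redundant when some already-kept gene ``fi`` earlier
    in the processing order satisfies SU(fi, C) >= SU(fj, C) and
    SU(fi, fj) >= SU(fj, C).  Removed genes never act as blankers.
    ``order="input"`` (default) walks F as listed — the pseudocode's
    ``for i, for j > i`` double loop; ``order="relevance"`` walks in
    descending SU(·, C), ties toward the smaller index.  Genes in
    ``protected`` are never removed (they still blanket others).
    Returns ``(kept, removed)`` in ascending gene-index order.
    """
    if len(F) == 0:
        raise ValueError("F must be nonempty")
    codes = view.codes if isinstance(view, DiscretizedView) else np.asarray(view)
    labels = np.asarray(labels)
    F = [int(g) for g in F]
    protected = set(int(g) for g in protected)

    su_c = {g: symmetric_uncertainty(codes[:, g], labels) for g in F}
    if order == "relevance":
        walk = sorted(F, key=lambda g: (-su_c[g], g))
    elif order == "input":
        walk = list(F)
    else:
        raise ValueError("order must be 'input' or 'relevance'")

    kept: list[int] = []
    removed: list[int] = []
    for fj in walk:
        blanketed = False
        if fj not in protected:
            for fi in kept:
                if su_c[fi] >= su_c[fj] and \
                        symmetric_uncertainty(codes[:, fi], codes[:, fj]) >= su_c[fj]:
                    blanketed = True
                    break
        (removed if blanketed else kept).append(fj)
    return sorted(kept), sorted(removed)


def complementarity_select(
    P: Sequence[int],
    pruned_F: Sequence[int],
    view: DiscretizedView | np.ndarray,
    labels: Sequence[int],
    mode: str = "interaction_gain",
    eps: float = 0.0,
) -> list[int]:
    """Retain genes whose class information grows when conditioned on a strong gene.

    ``mode="interaction_gain"`` (default): gene fj in ``pruned_F`` \\ ``P``
    is retained when max over pi in P of CMI(fj; C | pi) - I(fj; C)
    exceeds ``eps``.  ``mode="literal"`` reproduces the pseudocode's sign
    test, retaining fj when CMI(fj; C | pi) > eps for some pi (with eps
    standing in for the unreachable "< 0" branch of the plug-in
    estimator).  An empty P yields an empty result with a warning.
    """
    codes = view.codes if isinstance(view, DiscretizedView) else np.asarray(view)
    labels = np.asarray(labels)
    P = [int(g) for g in P]
    if not P:
        warnings.warn("no strong genes to condition on; nothing retained", RuntimeWarning)
        return []
    if mode not in ("interaction_gain", "literal"):
        raise ValueError("mode must be 'interaction_gain' or 'literal'")
    retained = []
    for fj in sorted(int(g) for g in pruned_F):
        if fj in P:
            continue
        marginal = mutual_information(codes[:, fj], labels)
        for pi in P:
            cmi = conditional_mutual_information(codes[:, fj], labels, codes[:, pi])
            score = cmi - marginal if mode == "interaction_gain" else cmi
            if score > eps:
                retained.append(fj)
                break
    return retained


def run_rcmf(data: LabeledDataset, cfg: RunConfig | None = None) -> CandidateSet:
    """Full stage 1: filter sets -> redundancy pruning -> complementarity.

    Deterministic given the data and config.  ``final`` is the ascending
    union of the surviving consensus genes and the complementary genes.
    """
    cfg = cfg or RunConfig()
    F, P, rankings = build_filter_sets(data, cfg.filter_top_n, cfg)
    view = discretize(data.values, n_bins=cfg.n_bins)
    kept, removed = redundancy_prune(F, view, data.labels, order=cfg.prune_order)
    strong = sorted(set(P) & set(kept))
    complementary = complementarity_select(
        strong, kept, view, data.labels,
        mode=cfg.complementarity_mode, eps=cfg.complementarity_eps,
    )
    final = sorted(set(strong) | set(complementary))
    return CandidateSet(strong=strong, complementary=sorted(complementary),
                        removed_redundant=removed, final=final, rankings=rankings)
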