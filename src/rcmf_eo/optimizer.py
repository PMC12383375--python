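"""Stage 2: binary Equilibrium Optimizer over the candidate gene space.

Particles carry continuous positions in [0, 1]^D over the D candidate
genes; a position component > 0.5 switches the gene on.  Each update
moves a particle toward a member of the equilibrium pool (the four best
solutions found so far plus their componentwise mean) through an
exponential contraction term F and a generation-rate term G.

The enhanced variant ("gbgpseo") adds, per iteration:

* an adaptive Gaussian-barebone / Cauchy mutation — with probability CR
  a component is redrawn from Normal(midpoint(particle, leader),
  |particle - leader|), otherwise it takes a Cauchy-scaled differential
  step off two donor particles; the mutant replaces the particle only if
  not worse (greedy);
* an mRMR-ordered gene-pruning local search applied to the current best
  particle with probability GPP — selected genes are tentatively removed
  from least to most important and a removal is kept when fitness does
  not worsen.

``variant="eo"`` disables both enhancements, giving the plain-EO
baseline.  All randomness flows through one ``numpy.random.Generator``,
so a run is a deterministic function of (data, candidates, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabeledDataset, RunConfig
from .evaluation import FitnessSpec, KnnCvFitness, RunResult, summarize_replicates
from .info_theory import discretize, mrmr_rank

__all__ = [
    "Particle",
    "EquilibriumPool",
    "initialize_swarm",
    "binarize",
    "repair_subset",
    "exponential_term",
    "time_coefficient",
    "generation_rate",
    "eo_step",
    "adaptive_cr",
    "barebone_mutation",
    "gene_pruning",
    "eo_iteration",
    "run_gbgpseo",
    "run_replicates",
]


@dataclass
class Particle:
    """Continuous position over the candidate space plus its binary subset."""

    position: np.ndarray
    subset: np.ndarray
    fitness: float = np.inf


class EquilibriumPool:
    """The four best solutions found so far plus their mean position.

    ``update`` performs the canonical cascade: a candidate strictly better
    than a stored solution shifts the worse ones down.  ``members()``
    returns the five attractor positions (unfilled slots fall back to the
    best available solution, which only matters in the first iterations
    of very small populations).
    """

    def __init__(self, dim: int):
        self.dim = dim
        self.fitnesses = [np.inf] * 4
        self.positions: list[np.ndarray | None] = [None] * 4
        self.subsets: list[np.ndarray | None] = [None] * 4

    def update(self, fitness: float, position: np.ndarray, subset: np.ndarray) -> None:
        for slot in range(4):
            if fitness < self.fitnesses[slot]:
                self.fitnesses.insert(slot, fitness)
                self.positions.insert(slot, position.copy())
                self.subsets.insert(slot, subset.copy())
                del self.fitnesses[4:], self.positions[4:], self.subsets[4:]
                return

    def members(self) -> list[np.ndarray]:
        filled = [p for p in self.positions if p is not None]
        if not filled:
            raise ValueError("pool is empty")
        four = [self.positions[i] if self.positions[i] is not None else filled[0]
                for i in range(4)]
        average = np.mean(np.stack(four), axis=0)
        return four + [average]

    @property
    def best_fitness(self) -> float:
        return self.fitnesses[0]

    @property
    def best_position(self) -> np.ndarray:
        if self.positions[0] is None:
            raise ValueError("pool is empty")
        return self.positions[0]

    @property
    def best_subset(self) -> np.ndarray:
        return self.subsets[0]


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Subset bit d is on iff position[d] > threshold."""
    return position > threshold


def repair_subset(position: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Never allow an all-zero subset: activate the largest-position dimension."""
    if not subset.any():
        subset = subset.copy()
        subset[int(np.argmax(position))] = True
    return subset


def initialize_swarm(
    D: int, pop: int, rng: np.random.Generator, threshold: float = 0.5
) -> list[Particle]:
    """Positions iid uniform on [0, 1]^D; an all-zero subset is repaired by
    activating one uniformly chosen dimension (its position is pushed
    above the threshold deterministically from its current value)."""
    if D < 1:
        raise ValueError("dimension must be >= 1")
    if pop < 1:
        raise ValueError("population must be >= 1")
    swarm = []
    for _ in range(pop):
        position = rng.random(D)
        subset = binarize(position, threshold)
        if not subset.any():
            j = int(rng.integers(D))
            position[j] = 0.5 + 0.5 * position[j] + 1e-9
            subset = binarize(position, threshold)
        swarm.append(Particle(position=position, subset=subset))
    return swarm


def time_coefficient(T: int, Miter: int, a2: float = 1.0) -> float:
    """t = (1 - T/Miter)^(a2 * T/Miter): 1 at T=0, 0 at T=Miter."""
    if Miter < 1:
        raise ValueError("Miter must be >= 1")
    frac = T / Miter
    return float((1.0 - frac) ** (a2 * frac))


def exponential_term(
    t: float,
    rng: np.random.Generator | None = None,
    size: int | None = None,
    a1: float = 2.0,
    r1: np.ndarray | None = None,
    r2: np.ndarray | None = None,
) -> np.ndarray:
    """F = a1 * sign(r1 - 0.5) * (exp(-r2 * t) - 1), componentwise.

    Draw order when ``rng`` is used: r1 then r2.
    """
    if r1 is None:
        r1 = rng.random(size)
    if r2 is None:
        r2 = rng.random(size)
    return a1 * np.sign(r1 - 0.5) * (np.exp(-r2 * t) - 1.0)


def generation_rate(
    xeq: np.ndarray,
    x: np.ndarray,
    F: np.ndarray,
    rng: np.random.Generator | None = None,
    gp: float = 0.5,
    rd1: np.ndarray | None = None,
    rd2: np.ndarray | None = None,
    r2: np.ndarray | None = None,
) -> np.ndarray:
    """G = -P ∘ (Xeq - r2 ∘ X) ∘ F with P = 0.5 * rd1 gated by rd2 >= GP.

    Draw order when ``rng`` is used: rd1, rd2, r2.
    """
    size = x.shape[0]
    if rd1 is None:
        rd1 = rng.random(size)
    if rd2 is None:
        rd2 = rng.random(size)
    if r2 is None:
        r2 = rng.random(size)
    P = 0.5 * rd1 * (rd2 >= gp)
    return -P * (xeq - r2 * x) * F


def eo_step(
    x: np.ndarray,
    xeq: np.ndarray,
    F: np.ndarray,
    G: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """X(T+1) = Xeq + (X - Xeq)∘F + (G / λ)·(1 - F), clamped to [0, 1].

    λ is floored at 1e-12 (the canonical update divides by λ∘V with V = 1).
    """
    new = xeq + (x - xeq) * F + (G / np.maximum(lam, 1e-12)) * (1.0 - F)
    return np.clip(new, 0.0, 1.0)


def adaptive_cr(T: int, Miter: int, cr_max: float = 1.0, cr_min: float = 0.0,
                direction: str = "decreasing") -> float:
    """CR = CRmax - (CRmax - CRmin) * T / Miter (Gaussian branch dominates
    early); ``direction="increasing"`` inverts the schedule."""
    frac = T / Miter
    if direction == "increasing":
        frac = 1.0 - frac
    return float(cr_max - (cr_max - cr_min) * frac)


def barebone_mutation(
    position: np.ndarray,
    leader: np.ndarray,
    donor1: np.ndarray,
    donor2: np.ndarray,
    cr: float,
    rng: np.random.Generator | None = None,
    r: np.ndarray | None = None,
    gauss: np.ndarray | None = None,
    cauchy: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-barebone / Cauchy mutant of one particle position.

    Component j takes Normal((leader_j + x_j)/2, |leader_j - x_j|) when
    r_j < cr, else x_j + k_j * (donor1_j - donor2_j) with k_j standard
    Cauchy.  Draw order when ``rng`` is used: r, standard-normal, cauchy.
    The result is clamped to [0, 1]; acceptance is the caller's business.
    """
    size = position.shape[0]
    if r is None:
        r = rng.random(size)
    if gauss is None:
        gauss = rng.standard_normal(size)
    if cauchy is None:
        cauchy = rng.standard_cauchy(size)
    mean = 0.5 * (leader + position)
    sd = np.abs(leader - position)
    gaussian_branch = mean + sd * gauss
    cauchy_branch = position + cauchy * (donor1 - donor2)
    return np.clip(np.where(r < cr, gaussian_branch, cauchy_branch), 0.0, 1.0)


def gene_pruning(
    particle: Particle,
    evaluator: KnnCvFitness,
    codes: np.ndarray,
    labels: np.ndarray,
    rho: float,
    gpp: float = 0.4,
    accept_ties: bool = True,
) -> Particle:
    """mRMR-ordered local search removing genes that do not help.

    Fires only when the pruning draw ``rho`` is below ``gpp``.  The
    selected genes are ranked by mRMR and traversed from least to most
    important; a tentative removal is kept when the pruned fitness is
    not worse (strictly better with ``accept_ties=False``).  The subset
    is never emptied.  Pruned dimensions have their position halved so
    the binary projection stays consistent with the subset.
    """
    if rho >= gpp:
        return particle
    selected = np.flatnonzero(particle.subset)
    if selected.size == 0:
        raise ValueError("particle has no selected gene")
    ranking = mrmr_rank(selected.tolist(), codes, labels)
    current = set(selected.tolist())
    fitness = particle.fitness
    for gene in reversed(ranking):  # least important first
        if len(current) == 1:
            break
        trial = sorted(current - {gene})
        trial_fit = evaluator.fitness(trial)
        if trial_fit < fitness or (accept_ties and trial_fit == fitness):
            current.remove(gene)
            fitness = trial_fit
    subset = np.zeros_like(particle.subset)
    subset[sorted(current)] = True
    position = particle.position.copy()
    position[~subset] = position[~subset] * 0.5
    return Particle(position=position, subset=subset, fitness=fitness)


def _evaluate(particle: Particle, evaluator: KnnCvFitness) -> None:
    particle.fitness = evaluator.fitness(np.flatnonzero(particle.subset))


def eo_iteration(
    swarm: list[Particle],
    pool: EquilibriumPool,
    t: float,
    rng: np.random.Generator,
    cfg: RunConfig,
    evaluator: KnnCvFitness,
) -> None:
    """One synchronous EO position update of the whole swarm.

    The pool membership is snapshotted at entry; every particle then
    draws, in order, a pool index (integers(5)), r1(D) and r2(D) for the
    exponential term, rd1(D), rd2(D) and r2(D) for the generation rate,
    and λ(D).  All particles are re-evaluated and the pool updated after
    the positions have moved (canonical synchronous scheme).
    """
    D = swarm[0].position.shape[0]
    members = pool.members()
    for p in swarm:
        xeq = members[int(rng.integers(5))]
        F = exponential_term(t, rng, D, a1=cfg.a1)
        G = generation_rate(xeq, p.position, F, rng, gp=cfg.GP)
        lam = rng.random(D)
        p.position = eo_step(p.position, xeq, F, G, lam)
        p.subset = repair_subset(p.position, binarize(p.position, cfg.binarize_threshold))
    for p in swarm:
        _evaluate(p, evaluator)
    for p in swarm:
        pool.update(p.fitness, p.position, p.subset)


def run_gbgpseo(
    data: LabeledDataset,
    candidates,
    cfg: RunConfig | None = None,
    variant: str = "gbgpseo",
    seed: int | None = None,
) -> RunResult:
    """One full wrapper run over ``candidates`` (a CandidateSet or index list).

    Randomness contract (one ``default_rng(seed)`` generator, consumed in
    this exact order): initialization draws one uniform(D) vector per
    particle plus, for an all-zero subset, one integer in [0, D); then
    per iteration and per particle the EO phase draws pool index
    (integers(5)), r1(D), r2(D) for F, rd1(D), rd2(D), r2(D) for G, and
    λ(D); the mutation phase (gbgpseo only) draws per particle two
    distinct donor indices (choice without replacement), r(D),
    standard-normal(D) and Cauchy(D); finally one uniform pruning draw ρ
    per iteration.  This contract is what makes an externally
    hand-computed iteration reproducible.

    Returns a single-replicate :class:`RunResult` with the best subset in
    original gene indices and the per-iteration best-so-far fitness trace
    (entry 0 is the initial population's best).
    """
    cfg = cfg or RunConfig()
    if variant not in ("gbgpseo", "eo"):
        raise ValueError("variant must be 'gbgpseo' or 'eo'")
    cand = list(getattr(candidates, "final", candidates))
    if not cand:
        raise ValueError("candidate set is empty")
    D = len(cand)
    seed = cfg.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)

    spec = FitnessSpec(n_candidates=D, alpha=cfg.alpha, knn_k=cfg.knn_k,
                       cv_folds=cfg.cv_folds, fold_seed=seed,
                       standardize=cfg.standardize)
    evaluator = KnnCvFitness(data.values[:, cand], data.labels, spec)
    codes = discretize(data.values[:, cand], n_bins=cfg.n_bins).codes

    swarm = initialize_swarm(D, cfg.population_size, rng, cfg.binarize_threshold)
    pool = EquilibriumPool(D)
    for p in swarm:
        _evaluate(p, evaluator)
        pool.update(p.fitness, p.position, p.subset)
    trace = [pool.best_fitness]

    pop = len(swarm)
    for T in range(1, cfg.max_iter + 1):
        t = time_coefficient(T, cfg.max_iter, cfg.a2)
        eo_iteration(swarm, pool, t, rng, cfg, evaluator)

        if variant == "gbgpseo":
            cr = adaptive_cr(T, cfg.max_iter, cfg.CRmax, cfg.CRmin, cfg.cr_direction)
            leader = pool.best_position
            for i, p in enumerate(swarm):
                if pop >= 3:
                    others = np.array([j for j in range(pop) if j != i])
                    d1, d2 = rng.choice(others, size=2, replace=False)
                    donor1, donor2 = swarm[d1].position, swarm[d2].position
                else:
                    donor1 = donor2 = p.position
                    rng.choice(np.arange(max(pop - 1, 1)), size=min(2, max(pop - 1, 1)),
                               replace=False)  # keep the draw count stable
                mutant_pos = barebone_mutation(p.position, leader, donor1, donor2, cr, rng)
                mutant_sub = repair_subset(mutant_pos, binarize(mutant_pos, cfg.binarize_threshold))
                mutant_fit = evaluator.fitness(np.flatnonzero(mutant_sub))
                if mutant_fit <= p.fitness:
                    p.position, p.subset, p.fitness = mutant_pos, mutant_sub, mutant_fit
                    pool.update(p.fitness, p.position, p.subset)
            rho = float(rng.random())
            best_i = int(np.argmin([p.fitness for p in swarm]))
            pruned = gene_pruning(swarm[best_i], evaluator, codes, data.labels,
                                  rho, cfg.GPP, cfg.prune_accept_ties)
            swarm[best_i] = pruned
            pool.update(pruned.fitness, pruned.position, pruned.subset)

        trace.append(pool.best_fitness)

    best_local = np.flatnonzero(pool.best_subset)
    best_subset = [cand[d] for d in best_local]
    accuracy = evaluator.accuracy(best_local)
    replicate = (accuracy, len(best_subset), pool.best_fitness)
    return RunResult(
        best_subset=best_subset,
        best_fitness=pool.best_fitness,
        trace=trace,
        replicates=[replicate],
        summary=summarize_replicates([replicate]),
        seed=seed,
        variant=variant,
    )


def run_replicates(
    data: LabeledDataset,
    candidates,
    cfg: RunConfig | None = None,
    variant: str = "gbgpseo",
    n_replicates: int | None = None,
) -> RunResult:
    """Independent replicate runs (seeds ``rng_seed + r``) with summary stats.

    The returned result carries the best replicate's subset/fitness/trace
    and the per-replicate (accuracy, size, fitness) tuples; MeanA, MeanS
    and MeanF summarize them.  Using the same base seed for two variants
    pairs their replicates for head-to-head comparison.
    """
    cfg = cfg or RunConfig()
    n_rep = cfg.n_replicates if n_replicates is None else n_replicates
    results = [run_gbgpseo(data, candidates, cfg, variant, seed=cfg.rng_seed + r)
               for r in range(n_rep)]
    replicates = [r.replicates[0] for r in results]
    best = min(results, key=lambda r: r.best_fitness)
    return RunResult(
        best_subset=best.best_subset,
        best_fitness=best.best_fitness,
        trace=best.trace,
        replicates=replicates,
        summary=summarize_replicates(replicates),
        seed=cfg.rng_seed,
        variant=variant,
    )
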