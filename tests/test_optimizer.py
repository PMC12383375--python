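"""Equilibrium-optimizer operators, mutation, pruning and full runs."""

import numpy as np
import pytest

from rcmf_eo import RunConfig, run_gbgpseo
from rcmf_eo.evaluation import FitnessSpec, KnnCvFitness
from rcmf_eo.optimizer import (
    EquilibriumPool,
    Particle,
    adaptive_cr,
    barebone_mutation,
    binarize,
    eo_iteration,
    eo_step,
    exponential_term,
    gene_pruning,
    generation_rate,
    initialize_swarm,
    repair_subset,
    time_coefficient,
)
from rcmf_eo.synthetic_data import SynthSpec, generate


# ------------------------------------------------------------ components


def test_time_coefficient_boundary_and_midpoint():
    assert time_coefficient(0, 100) == 1.0
    assert time_coefficient(100, 100) == 0.0
    assert time_coefficient(50, 100) == pytest.approx(np.sqrt(0.5), abs=1e-15)
    assert time_coefficient(50, 100, a2=2.0) == pytest.approx(0.5, abs=1e-15)


def test_exponential_term_zero_time_and_bound():
    rng = np.random.default_rng(0)
    assert np.all(exponential_term(0.0, rng, 50) == 0.0)
    t = 0.8
    F = exponential_term(t, rng, 10_000, a1=2.0)
    assert np.all(np.abs(F) <= 2.0 * (1 - np.exp(-t)) + 1e-15)


def test_exponential_term_sign_symmetric():
    from scipy.stats import chisquare

    rng = np.random.default_rng(1)
    F = exponential_term(0.5, rng, 10_000)
    pos = int((F > 0).sum())
    neg = int((F < 0).sum())
    assert chisquare([pos, neg]).pvalue > 1e-3


def test_generation_rate_gating_and_zero_factor():
    xeq = np.array([0.3, 0.6, 0.9])
    x = np.array([0.1, 0.5, 0.2])
    F = np.array([0.4, -0.2, 0.1])
    # all rd2 below GP -> zero branch
    G = generation_rate(xeq, x, F, gp=0.5,
                        rd1=np.full(3, 0.7), rd2=np.full(3, 0.2), r2=np.full(3, 0.3))
    assert np.all(G == 0.0)
    # F = 0 -> G = 0 regardless of the gate
    G = generation_rate(xeq, x, np.zeros(3), gp=0.0,
                        rd1=np.full(3, 0.7), rd2=np.full(3, 0.9), r2=np.full(3, 0.3))
    assert np.all(G == 0.0)
    # injected draws match the hand formula
    rd1, rd2, r2 = np.array([0.2, 0.8, 0.5]), np.array([0.6, 0.4, 0.9]), np.array([0.1, 0.7, 0.3])
    G = generation_rate(xeq, x, F, gp=0.5, rd1=rd1, rd2=rd2, r2=r2)
    P = 0.5 * rd1 * (rd2 >= 0.5)
    np.testing.assert_allclose(G, -P * (xeq - r2 * x) * F, atol=1e-15)


def test_eo_step_algebra():
    x = np.array([0.2, 0.4, 0.6])
    xeq = np.array([0.9, 0.1, 0.5])
    ones = np.ones(3)
    np.testing.assert_allclose(eo_step(x, xeq, ones, np.zeros(3), ones), x, atol=1e-15)
    np.testing.assert_allclose(eo_step(x, xeq, np.zeros(3), np.zeros(3), ones), xeq, atol=1e-15)
    out = eo_step(np.array([5.0]), np.array([5.0]), np.array([1.0]),
                  np.array([0.0]), np.array([1.0]))
    assert 0.0 <= out[0] <= 1.0                      # clamped


def test_adaptive_cr_schedule():
    assert adaptive_cr(0, 100) == 1.0
    assert adaptive_cr(100, 100) == 0.0
    assert adaptive_cr(25, 100) == pytest.approx(0.75)
    assert adaptive_cr(25, 100, direction="increasing") == pytest.approx(0.25)


def test_barebone_mutation_degenerate_branches():
    x = np.array([0.3, 0.7, 0.5])
    # leader == particle: Gaussian branch has sd 0 -> exactly the leader
    out = barebone_mutation(x, x, np.array([0.1, 0.1, 0.1]), np.array([0.9, 0.9, 0.9]),
                            cr=1.0, r=np.zeros(3), gauss=np.array([5.0, -3.0, 0.0]),
                            cauchy=np.zeros(3))
    np.testing.assert_allclose(out, x, atol=1e-15)
    # equal donors: Cauchy branch leaves the particle unchanged
    out = barebone_mutation(x, np.ones(3), x.copy(), x.copy(),
                            cr=0.0, r=np.ones(3), gauss=np.zeros(3),
                            cauchy=np.array([100.0, -50.0, 3.0]))
    np.testing.assert_allclose(out, x, atol=1e-15)
    # output always within bounds
    rng = np.random.default_rng(2)
    for _ in range(20):
        out = barebone_mutation(rng.random(5), rng.random(5), rng.random(5),
                                rng.random(5), cr=0.5, rng=rng)
        assert np.all((out >= 0) & (out <= 1))


def test_initialize_swarm_bounds_repair_and_determinism():
    rng = np.random.default_rng(3)
    swarm = initialize_swarm(50, 10, rng)
    assert len(swarm) == 10
    for p in swarm:
        assert np.all((p.position >= 0) & (p.position <= 1))
        assert p.subset.any()
    a = initialize_swarm(8, 4, np.random.default_rng(9))
    b = initialize_swarm(8, 4, np.random.default_rng(9))
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.position, pb.position)
    # D = 1: every subset is {gene 0} after repair
    for p in initialize_swarm(1, 20, np.random.default_rng(4)):
        assert p.subset.tolist() == [True]
    with pytest.raises(ValueError):
        initialize_swarm(0, 3, rng)


def test_repair_activates_largest_position_dimension():
    position = np.array([0.1, 0.45, 0.3])
    subset = binarize(position)
    assert not subset.any()
    repaired = repair_subset(position, subset)
    assert repaired.tolist() == [False, True, False]


# --------------------------------------------------- one-iteration oracle


class _StubFitness:
    """Deterministic toy fitness: small subsets of low-index genes win."""

    def fitness(self, subset):
        subset = np.asarray(subset)
        return float(subset.sum() + len(subset)) / 100.0


def test_eo_iteration_matches_hand_computed_update():
    """Full canonical EO iteration vs an inline replay of the contract."""
    D, pop, seed, t = 3, 4, 123, 0.7
    cfg = RunConfig()
    ev = _StubFitness()
    init = np.random.default_rng(77).random((pop, D))
    swarm = [Particle(position=p.copy(),
                      subset=repair_subset(p, binarize(p))) for p in init]
    for p in swarm:
        p.fitness = ev.fitness(np.flatnonzero(p.subset))
    pool = EquilibriumPool(D)
    for p in swarm:
        pool.update(p.fitness, p.position, p.subset)

    # independent pool snapshot: best four by fitness plus their mean
    order = sorted(range(pop), key=lambda i: swarm[i].fitness)
    best4 = [init[i].copy() for i in order[:4]]
    members = best4 + [np.mean(best4, axis=0)]

    rng = np.random.default_rng(seed)
    eo_iteration(swarm, pool, t, rng, cfg, ev)

    replay = np.random.default_rng(seed)
    for i in range(pop):
        idx = int(replay.integers(5))
        r1, r2 = replay.random(D), replay.random(D)
        rd1, rd2, r2g = replay.random(D), replay.random(D), replay.random(D)
        lam = replay.random(D)
        xeq = members[idx]
        F = 2.0 * np.sign(r1 - 0.5) * (np.exp(-r2 * t) - 1.0)
        P = 0.5 * rd1 * (rd2 >= 0.5)
        G = -P * (xeq - r2g * init[i]) * F
        expected = np.clip(xeq + (init[i] - xeq) * F
                           + (G / np.maximum(lam, 1e-12)) * (1.0 - F), 0.0, 1.0)
        np.testing.assert_allclose(swarm[i].position, expected, atol=1e-12)
        assert swarm[i].subset.any()


def test_eo_iteration_keeps_positions_in_bounds():
    rng = np.random.default_rng(5)
    ev = _StubFitness()
    swarm = initialize_swarm(6, 5, rng)
    pool = EquilibriumPool(6)
    for p in swarm:
        p.fitness = ev.fitness(np.flatnonzero(p.subset))
        pool.update(p.fitness, p.position, p.subset)
    for t in (1.0, 0.5, 0.1):
        eo_iteration(swarm, pool, t, rng, RunConfig(), ev)
        for p in swarm:
            assert np.all((p.position >= 0) & (p.position <= 1))
            assert p.subset.any()


# ----------------------------------------------------------- gene pruning


def _separable_evaluator(extra_duplicate=False, seed=6):
    spec = SynthSpec(n_samples_per_class=(15, 15), n_informative=2, effect_size=6.0,
                     n_redundant_per_informative=0, n_complementary_pairs=0,
                     n_noise=2, rng_seed=seed)
    ds, _ = generate(spec)
    values = ds.values
    if extra_duplicate:
        values = np.column_stack([values, values[:, 0]])
    ev = KnnCvFitness(values, ds.labels,
                      FitnessSpec(n_candidates=values.shape[1], cv_folds=5))
    from rcmf_eo.info_theory import discretize

    return ev, discretize(values, 5).codes, ds.labels


def test_gene_pruning_gated_by_probability():
    ev, codes, y = _separable_evaluator()
    subset = np.array([True, True, True, True])
    particle = Particle(position=np.full(4, 0.8), subset=subset,
                        fitness=ev.fitness([0, 1, 2, 3]))
    out = gene_pruning(particle, ev, codes, y, rho=0.9, gpp=0.4)
    assert out is particle                         # unchanged object, no search


def test_gene_pruning_drops_duplicate_and_never_worsens():
    ev, codes, y = _separable_evaluator(extra_duplicate=True)
    n = codes.shape[1]
    subset = np.ones(n, dtype=bool)
    particle = Particle(position=np.full(n, 0.9), subset=subset,
                        fitness=ev.fitness(list(range(n))))
    out = gene_pruning(particle, ev, codes, y, rho=0.0, gpp=0.4)
    assert out.fitness <= particle.fitness
    assert out.subset.sum() <= particle.subset.sum()
    assert out.subset.any()                        # never emptied
    assert not (out.subset[0] and out.subset[n - 1])   # one duplicate went
    # binary projection stays consistent with the halved positions
    np.testing.assert_array_equal(out.subset, binarize(out.position))


def test_gene_pruning_singleton_never_emptied():
    ev, codes, y = _separable_evaluator()
    subset = np.array([True, False, False, False])
    particle = Particle(position=np.array([0.9, 0.1, 0.1, 0.1]), subset=subset,
                        fitness=ev.fitness([0]))
    out = gene_pruning(particle, ev, codes, y, rho=0.0, gpp=1.0)
    assert out.subset.sum() == 1


# -------------------------------------------------------------- full runs


def test_run_zero_iterations_returns_initial_best(wrapper_fixture):
    ds, _ = wrapper_fixture
    cfg = RunConfig(max_iter=0, rng_seed=5)
    res = run_gbgpseo(ds, list(range(20)), cfg)
    assert len(res.trace) == 1
    assert res.best_fitness == res.trace[0]
    assert res.best_subset


def test_run_seeded_reproducibility(wrapper_fixture):
    ds, _ = wrapper_fixture
    cfg = RunConfig(max_iter=10, rng_seed=2)
    a = run_gbgpseo(ds, list(range(30)), cfg)
    b = run_gbgpseo(ds, list(range(30)), cfg)
    assert a.trace == b.trace
    assert a.best_subset == b.best_subset
    assert a.best_fitness == b.best_fitness


@pytest.mark.parametrize("variant", ["eo", "gbgpseo"])
def test_run_trace_non_increasing(wrapper_fixture, variant):
    ds, _ = wrapper_fixture
    for seed in range(3):
        cfg = RunConfig(max_iter=15, rng_seed=seed)
        res = run_gbgpseo(ds, list(range(40)), cfg, variant=variant)
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))
        assert len(res.trace) == 16


def test_run_rejects_bad_inputs(wrapper_fixture):
    ds, _ = wrapper_fixture
    with pytest.raises(ValueError):
        run_gbgpseo(ds, [], RunConfig())
    with pytest.raises(ValueError):
        run_gbgpseo(ds, [0, 1], RunConfig(), variant="pso")


def test_fitness_consistency_of_reported_replicates(wrapper_fixture):
    """MeanF decomposes into alpha*error + size penalty for each replicate."""
    ds, _ = wrapper_fixture
    cfg = RunConfig(max_iter=10, rng_seed=4)
    cand = list(range(25))
    res = run_gbgpseo(ds, cand, cfg)
    acc, size, fit = res.replicates[0]
    spec = FitnessSpec(n_candidates=len(cand), alpha=cfg.alpha, knn_k=cfg.knn_k,
                       cv_folds=cfg.cv_folds, fold_seed=res.seed,
                       standardize=cfg.standardize)
    ev = KnnCvFitness(ds.values[:, cand], ds.labels, spec)
    local = [cand.index(g) for g in res.best_subset]
    assert fit == pytest.approx(cfg.alpha * (1 - acc) + (1 - cfg.alpha) * size / len(cand),
                                abs=1e-12)
    assert ev.fitness(local) == pytest.approx(fit, abs=1e-12)
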