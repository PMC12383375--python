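# Methods

This note documents the models, estimators, defaults and design choices
behind `rcmf_eo`, in the spirit of a package vignette: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Problem setting

Input is a labeled expression matrix: n samples × G genes of continuous
values with a categorical class per sample (k ≥ 2, every class with at
least two members so stratified cross-validation is defined). The goal
is a small gene subset that classifies well and is *stable* — repeated
runs on the same data must select the same genes, because a wrapper
search downstream of an unstable filter inherits its noise.

## Stage 1: the multi-filter ensemble

### The five filters

All filters score raw expression values; scaling enters only where a
distance does.

* **Fisher score** — between-class scatter over pooled within-class
  scatter, with the *population* (divide-by-n_k) within-class variance.
  A gene that is constant within every class but differs between classes
  scores +∞ and ranks first; a fully constant gene scores 0.
* **ReliefF** — k = 10 nearest hits/misses per probe, all samples used
  as probes (deterministic), features min-max scaled to [0, 1], Manhattan
  neighbor distance, misses weighted by class priors. These are the
  standard ReliefF conventions; the method itself fixes none of them.
* **Chi-square** — class × bin contingency on the shared discretization
  (below); zero-expectation cells contribute nothing.
* **|Pearson|** — absolute correlation with the integer class code; both
  correlation signs indicate relevance, and a constant gene scores 0.
* **Diagonal NCA** — one weight per gene, learned by maximizing the
  expected leave-one-out soft-neighbor classification objective with an
  L2 penalty (λ = 0.01) by gradient ascent from all-ones, with
  backtracking line search (accepted steps never decrease the
  objective; 50 iterations by default). Distances use z-scored values;
  the reported score is the squared weight. The run is deterministic.

Top-N lists (N = 100 by default; ties broken toward the smaller gene
index) feed the ensemble. N is deliberately generous: its job is recall,
not precision.

### Discretization

Every information-theoretic quantity — SU, MI, CMI, mRMR, chi-square —
operates on one shared equal-frequency discretization with 5 bins
(values tied with a boundary fall in the lower bin). One shared view
keeps all stage-1 decisions mutually consistent; equal-frequency binning
is robust to the skewed intensity distributions typical of expression
data. Probabilities are plug-in maximum-likelihood estimates with no
smoothing, and all logarithms are base 2 (everything is in bits). The
plug-in CMI is non-negative by construction, which is why the
complementarity rule below is a threshold test rather than a sign test.

### Redundancy pass

Over the union F of the five top-N lists, walked in listed order
(ascending gene index — the literal double loop of the pseudocode), gene
f_j is removed when an earlier-*kept* gene f_i satisfies
SU(f_i,C) ≥ SU(f_j,C) and SU(f_i,f_j) ≥ SU(f_j,C): f_i approximately
Markov-blankets f_j. Removed genes never act as blankers. No gene is
protected: consensus genes can blanket one another, which is what lets
the pass discard redundant copies that all five filters nominate. An
FCBF-style `order="relevance"` walk (descending class-SU) is available;
it is *not* the default because with finite-sample SU a noisy copy
out-scores its parent roughly half the time, so the relevance walk keeps
a random family member rather than the parent, while the listed-order
walk is deterministic about which member survives.

### Complementarity pass

Survivors outside the strong (all-five consensus ∩ kept) set are kept
when conditioning on some strong gene increases their class information:
max over strong p of CMI(f_j;C|p) − I(f_j;C) > ε. Default ε = 0; on
small samples the plug-in estimates carry positive bias (conditioning
fragments the data), so ε = 0 is permissive and a user wanting a tighter
candidate set should raise ε to ≈ 0.05. A `mode="literal"` reproduces
the published sign test with ε standing in for the unreachable "< 0"
branch. If the strong set is empty the pass returns nothing, with a
warning.

The candidate set handed to stage 2 is strong ∪ complementary, in
ascending gene order, with full provenance retained. The whole stage is
a deterministic function of (data, config) — its repeat-run Jaccard
stability is exactly 1 by construction, and the tests assert it.

## Stage 2: the enhanced Equilibrium Optimizer

### Representation and fitness

Particles are continuous positions in [0,1]^D over the D candidates;
component > 0.5 selects the gene. An all-zero projection is repaired by
activating the largest-position component (at initialization, a
uniformly chosen one). Fitness (lower is better) is

    α·E(s) + (1−α)·R/N,  α = 0.9, R = |s|, N = D,

with E(s) the pooled misclassification error of 5-NN under 10-fold
stratified CV. The CV partition is fixed once per run, making fitness a
deterministic, memoized function of the subset — the prerequisite for a
monotone convergence trace. KNN distances use per-fold z-scoring from
training-fold statistics (configurable off); ties are deterministic
(equal distance → smaller training index; tied vote → smaller class
code). Reported accuracy (MeanA) is 1 − E(s) from the same CV.

With the error quantum 1/n (one sample) usually exceeding the per-gene
size credit (1−α)/N, removals are accepted in practice only when the
error does not increase; the size term acts as a tie-breaker toward
smaller subsets, which is exactly the role it needs for pruning.

### EO core

Canonical equilibrium-pool dynamics: pool = four best solutions so far +
their mean; per particle per iteration, a pool member X_eq is drawn
uniformly and

    F = a1·sign(r1−0.5)·(exp(−r2·t) − 1),  t = (1 − T/M)^(a2·T/M),
    G = −P∘(X_eq − r2'∘X)∘F,  P = 0.5·r_d1 gated by r_d2 ≥ GP,
    X ← clip( X_eq + (X−X_eq)∘F + (G/λ)·(1−F), 0, 1 ),  λ = r3 (floored at 1e-12).

Defaults a1 = 2, a2 = 1, GP = 0.5, population 10, 100 iterations. The
update is synchronous (pool snapshotted per iteration) and the exact
order in which random draws are consumed is documented in
`run_gbgpseo`'s docstring so an external replay can reproduce an
iteration bit-for-bit — the test suite and the acceptance script both do.

### Gaussian-barebone / Cauchy mutation

Per particle and component: with probability CR a Gaussian barebone draw
N((X_leader+X)/2, |X_leader−X|); otherwise a Cauchy-scaled differential
step X + k·(X_a − X_b) off two distinct donors (k standard Cauchy, drawn
per component). Mutants replace their particle only when not worse —
unconditional replacement would break the monotone trace. CR follows the
linear schedule between CRmax = 1 and CRmin = 0; the *direction* defaults
to exploration-first (Cauchy branch dominant early, Gaussian late,
`cr_direction="increasing"`). The printed linear decay applied verbatim
does the opposite, and measurably hurts: under it the enhanced wrapper
ends above plain EO's fitness in roughly one replicate in ten (early
Gaussian collapse onto the leader, late Cauchy jumps almost always
rejected), while the exploration-first direction dominates plain EO
uniformly. Both behaviours remain selectable.

### mRMR gene pruning

Once per iteration, with probability GPP = 0.4, the best particle's
selected genes are ranked by greedy mRMR (relevance I(g;C) minus mean MI
with already-ranked genes, on the shared discretization) and traversed
from least to most important; each tentative removal is kept when
fitness does not worsen (strictness configurable). The subset is never
emptied. Pruning the single current best particle once per iteration
keeps the local search affordable; pruning every particle would
multiply fitness evaluations several-fold for little gain. A fitness
"score threshold 0.3" sometimes mentioned alongside this strategy has no
operational definition and is not implemented.

`variant="eo"` disables mutation and pruning, giving the plain-EO
baseline used in the head-to-head comparisons. Replicate experiments
reuse one base seed (replicate r runs with seed base+r), so two variants
run over the same seeds form paired comparisons.

## Synthetic data

The generator plants four gene roles in a class-conditional model:

* **informative** — N(c·effect, 1) per class c, effect = 1.5 sd by
  default (a clearly differentially expressed marker);
* **redundant** — parent + N(0, 0.3): a strongly correlated copy;
* **complementary pairs** — an XOR interaction over latent bits. The
  *partner* bit is Bernoulli(0.15), independent of the class; the
  *anchor* bit is partner ⊕ class-bit. Bits map to bimodal values
  (separation 2.0, cluster sd 0.3, i.e. ≈ 6.7σ — bit recovery is
  essentially error-free, so the pair's information content is governed
  by the flip probability alone). Marginally the partner carries ~0 bits
  about the class while CMI(partner; C | anchor) = H(0.15) ≈ 0.61 bits;
  the anchor carries ≈ 0.39 bits of marginal signal. The anchor *must*
  be marginally visible: a fully symmetric pair (both members silent) is
  invisible to every univariate filter, so no pair member could ever
  enter the candidate union and the complementarity pass would have
  nothing to rescue — anchored XOR is the weakest planted interaction
  this pipeline can detect by design. The flip probability is set so the
  anchor's class-SU (~0.24 plug-in at n = 120) clears the spurious
  cross-SU band of unrelated strong genes (~0.10–0.16), keeping it out
  of chance Markov blankets;
* **noise** — N(0, 1), class-independent.

Named benchmark fixtures (regenerated from fixed seeds at test time,
never stored): `small` 40×30, `rcmf` 120×500 (10 informative + 3 copies
each + 2 XOR pairs + 456 noise), `wrapper` 100×60 (6 informative). The
problem sizes are chosen so the full suite and the acceptance script
re-run everything from scratch in a few minutes on one CPU.

What passing on these fixtures shows: correct estimators, a stable and
structure-recovering ensemble, a wrapper that dominates its own baseline
under the stated fitness. What it does not show: behaviour under
platform-specific noise (dye bias, probe effects, batch structure),
heavy class imbalance beyond unequal class counts, or p ≫ 10³ scaling —
real microarray studies should treat the defaults as starting points.

## Numerical conventions and degenerate inputs

* SU of two constant variables is defined as 0; CMI and MI are clipped
  at 0 against floating-point cancellation.
* Fisher +∞ scores sort above all finite scores, among themselves by
  ascending index; all ranking ties break toward the smaller index.
* KNN z-scoring replaces zero training-fold standard deviations with 1.
* λ in the EO update is floored at 1e-12; positions are clamped to
  [0, 1] after every operator.
* The Gaussian mutation with leader = particle is exactly the leader
  (sd = 0); equal donors make the Cauchy branch the identity.
* Label codes are assigned by sorted original label, so the encoding is
  reproducible across loads.
* Missing values are rejected at load time unless mean imputation is
  explicitly requested.

## Known limitations

* Plug-in information estimates are biased upward on small samples; the
  default ε = 0 complementarity test is therefore permissive (noise
  genes can slip into the candidate set — harmless to the wrapper, which
  prunes them, but candidate sets are larger than the "true" structure).
* The redundancy pass depends on the listed order of the union F; two
  datasets differing only by column order can keep different (equally
  redundant) family representatives.
* Diagonal NCA optimizes a non-concave objective; determinism comes from
  the fixed initialization, not from global optimality.
* AUC is computed from hard predictions, (1 + TPR − FPR)/2 — the
  published formula — not the rank-based ROC area; the two agree only
  for hard classifiers.
* Wrapper cost scales linearly in population × iterations × fold count;
  for candidate sets ≫ 10³ genes the KNN evaluator's per-fold caching
  dominates memory (folds × n × G doubles).
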