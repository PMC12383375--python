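"""Microarray-like synthetic datasets with planted ground truth.

The generator instantiates the three gene relationships the stage-1
ensemble is designed to handle, plus background noise:

* informative genes — class-conditional Gaussians whose class means are
  separated by ``effect_size`` standard deviations;
* redundant genes — an informative parent plus independent Gaussian
  noise of sd ``redundant_noise_sd`` (a noisy copy);
* complementary pairs — an XOR interaction: the *partner* gene's latent
  bit is Bernoulli(``xor_flip_prob``), independent of the class, and the
  *anchor* gene's bit is partner-bit XOR class-bit.  The anchor therefore
  agrees with the class bit with probability 1 - xor_flip_prob (it
  carries enough marginal signal for univariate filters to find it),
  while the partner is marginally uninformative and becomes visible only
  through CMI(partner; class | anchor);
* noise genes — standard Gaussians independent of the class.

All values are continuous.  Generation is deterministic given
``rng_seed``; fixtures are regenerated from their seeds at test time and
never stored as data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data_io import LabeledDataset

__all__ = ["SynthSpec", "GroundTruth", "generate", "standard_fixtures", "make_fixture"]

ROLE_INFORMATIVE = "informative"
ROLE_REDUNDANT = "redundant"
ROLE_COMPLEMENTARY = "complementary"
ROLE_NOISE = "noise"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-structure generator."""

    n_samples_per_class: tuple[int, ...] = (60, 60)
    n_informative: int = 10
    effect_size: float = 1.5
    n_redundant_per_informative: int = 3
    redundant_noise_sd: float = 0.3
    n_complementary_pairs: int = 2
    n_noise: int = 456
    xor_flip_prob: float = 0.15
    pair_separation: float = 2.0
    pair_noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if min(self.n_informative, self.n_redundant_per_informative,
               self.n_complementary_pairs, self.n_noise) < 0:
            raise ValueError("gene counts must be >= 0")
        if self.total_genes == 0:
            raise ValueError("spec defines zero genes")
        if len(self.n_samples_per_class) < 2 or min(self.n_samples_per_class) < 2:
            raise ValueError("need >= 2 classes with >= 2 samples each")
        if not 0 < self.xor_flip_prob < 0.5:
            raise ValueError("xor_flip_prob must lie in (0, 0.5)")

    @property
    def total_genes(self) -> int:
        return (self.n_informative * (1 + self.n_redundant_per_informative)
                + 2 * self.n_complementary_pairs + self.n_noise)

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_class)


@dataclass
class GroundTruth:
    """Per-gene role annotation of a generated dataset.

    ``partner[g]`` is the parent index for a redundant gene and the pair
    partner index for a complementary gene, else -1.  For complementary
    pairs ``anchor[g]`` is True for the member whose bit tracks the class.
    """

    roles: list[str]
    partner: list[int] = field(default_factory=list)
    anchor: list[bool] = field(default_factory=list)

    def of_role(self, role: str) -> list[int]:
        return [g for g, r in enumerate(self.roles) if r == role]

    @property
    def informative(self) -> list[int]:
        return self.of_role(ROLE_INFORMATIVE)

    @property
    def redundant(self) -> list[int]:
        return self.of_role(ROLE_REDUNDANT)

    @property
    def complementary(self) -> list[int]:
        return self.of_role(ROLE_COMPLEMENTARY)

    @property
    def noise(self) -> list[int]:
        return self.of_role(ROLE_NOISE)

    @property
    def complementary_pairs(self) -> list[tuple[int, int]]:
        seen = set()
        pairs = []
        for g in self.complementary:
            if g in seen:
                continue
            p = self.partner[g]
            pairs.append((g, p))
            seen.update((g, p))
        return pairs


def generate(spec: SynthSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Draw one dataset from ``spec``; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_samples
    labels = np.concatenate([
        np.full(cnt, c, dtype=np.int64) for c, cnt in enumerate(spec.n_samples_per_class)
    ])
    g_total = spec.total_genes
    values = np.empty((n, g_total), dtype=float)
    roles = [ROLE_NOISE] * g_total
    partner = [-1] * g_total
    anchor = [False] * g_total

    col = 0
    informative_cols = []
    for _ in range(spec.n_informative):
        values[:, col] = rng.normal(labels * spec.effect_size, 1.0)
        roles[col] = ROLE_INFORMATIVE
        informative_cols.append(col)
        col += 1

    for parent in informative_cols:
        for _ in range(spec.n_redundant_per_informative):
            values[:, col] = values[:, parent] + rng.normal(0.0, spec.redundant_noise_sd, n)
            roles[col] = ROLE_REDUNDANT
            partner[col] = parent
            col += 1

    y_bit = labels % 2
    for _ in range(spec.n_complementary_pairs):
        flip = rng.random(n) < spec.xor_flip_prob
        partner_bit = flip.astype(int)          # independent of the class
        anchor_bit = partner_bit ^ y_bit        # partner XOR anchor == class bit
        a_col, b_col = col, col + 1
        values[:, a_col] = partner_bit * spec.pair_separation + rng.normal(0, spec.pair_noise_sd, n)
        values[:, b_col] = anchor_bit * spec.pair_separation + rng.normal(0, spec.pair_noise_sd, n)
        roles[a_col] = roles[b_col] = ROLE_COMPLEMENTARY
        partner[a_col], partner[b_col] = b_col, a_col
        anchor[b_col] = True
        col += 2

    for _ in range(spec.n_noise):
        values[:, col] = rng.normal(0.0, 1.0, n)
        col += 1
    assert col == g_total

    dataset = LabeledDataset(
        values=values,
        labels=labels,
        gene_ids=[f"g{i:04d}" for i in range(g_total)],
        sample_ids=[f"s{i:04d}" for i in range(n)],
        label_names=list(range(len(spec.n_samples_per_class))),
    )
    return dataset, GroundTruth(roles=roles, partner=partner, anchor=anchor)


#: The named fixture specs used throughout the test suite.
#: "small"   — 40 x 30, for brute-force oracle tests.
#: "rcmf"    — 120 x 500 (10 informative, 3 copies each, 2 XOR pairs, 456 noise),
#:             the stage-1 structure-recovery benchmark.
#: "wrapper" — 100 x 60 candidates (6 informative), the stage-2 replicate benchmark.
_FIXTURES: dict[str, SynthSpec] = {
    "small": SynthSpec(
        n_samples_per_class=(20, 20), n_informative=4, n_redundant_per_informative=1,
        n_complementary_pairs=1, n_noise=20, rng_seed=11,
    ),
    "rcmf": SynthSpec(
        n_samples_per_class=(60, 60), n_informative=10, n_redundant_per_informative=3,
        n_complementary_pairs=2, n_noise=456, rng_seed=7,
    ),
    "wrapper": SynthSpec(
        n_samples_per_class=(50, 50), n_informative=6, n_redundant_per_informative=0,
        n_complementary_pairs=0, n_noise=54, rng_seed=23,
    ),
}


def standard_fixtures() -> dict[str, SynthSpec]:
    """Specs of the named fixtures (regenerate with :func:`generate`)."""
    return dict(_FIXTURES)


def make_fixture(name: str, seed: Optional[int] = None) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a named fixture, optionally overriding its seed."""
    spec = _FIXTURES[name]
    if seed is not None:
        spec = replace(spec, rng_seed=seed)
    return generate(spec)
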