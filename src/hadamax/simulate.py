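"""Simulated multiallelic fitness landscapes with known ground truth.

The generator emulates a combinatorially complete DMS-style experiment:
a DNA 6-mer (four states per position, 4^6 = 4,096 genotypes) whose
genetic architecture is sparse and low-order.  Single-substitution
effects are drawn from N(-1, 2^2) — matching the empirical tendency of
single mutants to be detrimental and larger than interaction terms —
pairwise background-averaged interaction terms are drawn from N(0, 1)
at three chosen position pairs, and all other coefficients (including
every order above two) are zero.  Phenotypes are the inverse transform
of the truth vector plus i.i.d. Gaussian measurement noise with
standard deviation ``noise_sd`` (default 2; 1 and 3 give the low/high
noise variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epistasis import CoefficientSet, Landscape, reconstruct
from .state_space import StateSpace

__all__ = ["SimulationConfig", "SimulatedLandscape", "draw_ground_truth", "simulate_landscape"]


@dataclass
class SimulationConfig:
    """Parameters of the simulated landscape.

    ``interacting_pairs`` uses 1-based positions; defaults reproduce the
    standard simulation (pairs [1,2], [3,5], [5,6]).
    """

    space: StateSpace = field(default_factory=lambda: StateSpace((4,) * 6))
    interacting_pairs: tuple[tuple[int, int], ...] = ((1, 2), (3, 5), (5, 6))
    first_order_mean: float = -1.0
    first_order_sd: float = 2.0
    pairwise_mean: float = 0.0
    pairwise_sd: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.space.n_positions
        pairs = []
        for a, b in self.interacting_pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) is not allowed")
            if not (1 <= a <= n and 1 <= b <= n):
                raise ValueError(f"pair ({a}, {b}) outside positions 1..{n}")
            pairs.append(tuple(sorted((int(a), int(b)))))
        self.interacting_pairs = tuple(pairs)
        if self.first_order_sd <= 0 or self.pairwise_sd <= 0:
            raise ValueError("distribution standard deviations must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "state_counts": list(self.space.state_counts),
            "interacting_pairs": [list(p) for p in self.interacting_pairs],
            "first_order_dist": {"mean": self.first_order_mean, "sd": self.first_order_sd},
            "pairwise_dist": {"mean": self.pairwise_mean, "sd": self.pairwise_sd},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            space=StateSpace(tuple(d.get("state_counts", (4,) * 6))),
            interacting_pairs=tuple(
                tuple(p) for p in d.get("interacting_pairs", ((1, 2), (3, 5), (5, 6)))
            ),
            first_order_mean=d.get("first_order_dist", {}).get("mean", -1.0),
            first_order_sd=d.get("first_order_dist", {}).get("sd", 2.0),
            pairwise_mean=d.get("pairwise_dist", {}).get("mean", 0.0),
            pairwise_sd=d.get("pairwise_dist", {}).get("sd", 1.0),
            noise_sd=d.get("noise_sd", 2.0),
            seed=d.get("seed", 0),
        )


@dataclass
class SimulatedLandscape:
    """Noisy landscape plus the ground-truth coefficients that made it."""

    landscape: Landscape
    truth: CoefficientSet
    config: SimulationConfig


def draw_ground_truth(config: SimulationConfig) -> CoefficientSet:
    """Draw the sparse ground-truth coefficient vector.

    Draw order is fixed (first-order terms by rank, then pairwise terms
    by rank) so results are bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    space = config.space
    vectors = space.all_genotypes()
    orders = (vectors != 0).sum(axis=1)
    eps = np.zeros(space.total_size)

    first = orders == 1
    eps[first] = rng.normal(config.first_order_mean, config.first_order_sd, first.sum())

    pair_set = set(config.interacting_pairs)
    second = np.nonzero(orders == 2)[0]
    for idx in second:
        pos = tuple(np.nonzero(vectors[idx])[0] + 1)
        if pos in pair_set:
            eps[idx] = rng.normal(config.pairwise_mean, config.pairwise_sd)
    return CoefficientSet(space, eps)


def simulate_landscape(config: SimulationConfig) -> SimulatedLandscape:
    """Ground truth -> noise-free phenotypes -> additive Gaussian noise.

    The landscape's error column is the known ``noise_sd`` for every
    genotype, mirroring how per-variant technical errors from a DMS
    pipeline are consumed downstream (maximum explainable variance).
    Noise draws use the same seeded generator as the truth draws, in
    rank order, after all coefficient draws.
    """
    rng = np.random.default_rng(config.seed)
    space = config.space
    vectors = space.all_genotypes()
    orders = (vectors != 0).sum(axis=1)
    eps = np.zeros(space.total_size)
    first = orders == 1
    eps[first] = rng.normal(config.first_order_mean, config.first_order_sd, first.sum())
    pair_set = set(config.interacting_pairs)
    for idx in np.nonzero(orders == 2)[0]:
        pos = tuple(np.nonzero(vectors[idx])[0] + 1)
        if pos in pair_set:
            eps[idx] = rng.normal(config.pairwise_mean, config.pairwise_sd)
    truth = CoefficientSet(space, eps)

    y = reconstruct(truth).phenotype_vector()
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, space.total_size)
    land = Landscape.from_vector(space, y, np.full(space.total_size, config.noise_sd))
    return SimulatedLandscape(land, truth, config)
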