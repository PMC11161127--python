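"""Genotype and coefficient indexing for multiallelic landscapes.

A combinatorially complete landscape over ``n`` sequence positions, with
``s_k`` possible alleles (states) at position ``k``, contains
``prod(s_k)`` genotypes.  Alleles are opaque integer states ``0..s_k-1``
where ``0`` is the wild-type allele.  Genotypes are ordered by their
mixed-radix integer representation with position 1 the most significant
digit, so the wild-type genotype ``(0, ..., 0)`` has rank 1 and the first
``s_n`` genotypes vary only at the last position.

Epistatic coefficients are indexed by the same vectors: a ``0`` entry
marks a position averaged over all backgrounds (displayed as ``*``) and a
nonzero entry names a specific mutated allele.  The *order* of a
coefficient is its number of nonzero entries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod

import numpy as np

__all__ = [
    "StateSpace",
    "index_of",
    "genotype_of",
    "order_of",
    "enumerate_coefficients",
    "count_coefficients",
]


@dataclass(frozen=True)
class StateSpace:
    """Per-position allele counts defining the genotype ordering.

    Parameters
    ----------
    state_counts
        One integer ``s_k >= 2`` per position.  A homogeneous landscape
        with ``s`` states at each of ``n`` positions is simply
        ``StateSpace((s,) * n)``.
    """

    state_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(s) for s in self.state_counts)
        if len(counts) < 1:
            raise ValueError("a state space needs at least one position")
        if any(s < 2 for s in counts):
            raise ValueError(f"every position needs >= 2 states, got {counts}")
        object.__setattr__(self, "state_counts", counts)

    @property
    def n_positions(self) -> int:
        return len(self.state_counts)

    @property
    def total_size(self) -> int:
        """Number of genotypes, ``prod(s_k)``."""
        return prod(self.state_counts)

    def validate_genotype(self, alleles) -> tuple[int, ...]:
        """Check a per-position allele vector, returning it as a tuple."""
        g = tuple(int(a) for a in alleles)
        if len(g) != self.n_positions:
            raise ValueError(
                f"genotype length {len(g)} != number of positions {self.n_positions}"
            )
        for k, (a, s) in enumerate(zip(g, self.state_counts), start=1):
            if not 0 <= a < s:
                raise ValueError(
                    f"allele {a} at position {k} out of range [0, {s - 1}]"
                )
        return g

    def all_genotypes(self) -> np.ndarray:
        """All genotypes in rank order as a ``(total_size, n)`` array."""
        idx = np.unravel_index(np.arange(self.total_size), self.state_counts)
        return np.stack(idx, axis=1)

    def __iter__(self):
        return iter(self.state_counts)

    def __len__(self) -> int:
        return len(self.state_counts)


def index_of(genotype, space: StateSpace) -> int:
    """1-based rank of a genotype in the mixed-radix ordering.

    ``rank = 1 + sum_k g_k * prod_{m>k} s_m``; the wild-type genotype is
    rank 1.
    """
    g = space.validate_genotype(genotype)
    return 1 + int(np.ravel_multi_index(g, space.state_counts))


def genotype_of(rank: int, space: StateSpace) -> tuple[int, ...]:
    """Inverse of :func:`index_of`: the allele vector at a 1-based rank."""
    rank = int(rank)
    if not 1 <= rank <= space.total_size:
        raise ValueError(f"rank {rank} out of range [1, {space.total_size}]")
    return tuple(int(a) for a in np.unravel_index(rank - 1, space.state_counts))


def order_of(states) -> int:
    """Number of nonzero (mutated / non-averaged) entries of a vector."""
    return int(sum(1 for a in states if a != 0))


def count_coefficients(space: StateSpace, max_order: int) -> int:
    """Number of coefficient ids of order <= ``max_order``.

    Equals ``sum over position subsets P with |P| <= max_order of
    prod_{k in P} (s_k - 1)``.
    """
    _check_order(space, max_order)
    total = 0
    for k in range(max_order + 1):
        for subset in itertools.combinations(space.state_counts, k):
            total += prod(s - 1 for s in subset)
    return total


def enumerate_coefficients(space: StateSpace, max_order: int) -> np.ndarray:
    """All coefficient ids with order <= ``max_order`` in rank order.

    Returns a ``(count, n)`` integer array of state vectors (0 marks an
    averaged position).  Generated subset-by-subset rather than by
    filtering all ``total_size`` ids, so large spaces with small
    ``max_order`` stay cheap.
    """
    _check_order(space, max_order)
    n = space.n_positions
    ids: list[tuple[int, ...]] = []
    for k in range(max_order + 1):
        for positions in itertools.combinations(range(n), k):
            ranges = [range(1, space.state_counts[p]) for p in positions]
            for alleles in itertools.product(*ranges):
                vec = [0] * n
                for p, a in zip(positions, alleles):
                    vec[p] = a
                ids.append(tuple(vec))
    arr = np.array(ids, dtype=np.int64).reshape(len(ids), n)
    ranks = np.ravel_multi_index(arr.T, space.state_counts)
    return arr[np.argsort(ranks, kind="stable")]


def ranks_of(vectors: np.ndarray, space: StateSpace) -> np.ndarray:
    """1-based ranks of an ``(m, n)`` array of state vectors."""
    vectors = np.asarray(vectors)
    return np.ravel_multi_index(vectors.T, space.state_counts) + 1


def vectors_of(ranks, space: StateSpace) -> np.ndarray:
    """State vectors of an array of 1-based ranks, shape ``(m, n)``."""
    r = np.asarray(ranks, dtype=np.int64)
    if r.size and (r.min() < 1 or r.max() > space.total_size):
        raise ValueError("rank out of range")
    return np.stack(np.unravel_index(r - 1, space.state_counts), axis=-1)


def _check_order(space: StateSpace, max_order: int) -> None:
    if not 0 <= max_order <= space.n_positions:
        raise ValueError(
            f"max_order {max_order} out of range [0, {space.n_positions}]"
        )
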