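"""Enrichment of physical contacts among inferred genetic interactions.

Given the non-zero epistatic coefficients of a fitted sparse model, the
position pairs they implicate (every unordered pair of mutated positions
within each coefficient of order >= 2) are tested for enrichment of a
supplied set of physically interacting position pairs (e.g. Watson-Crick
base pairs or residue contacts) with Fisher's exact test.  The
background is the multiset of position pairs contained in *all possible*
epistatic coefficients up to the model's order, so a pair contained in
many retained coefficients counts as many occurrences; the observed
occurrences are compared against the background occurrences split by
contact membership.  :func:`position_pairs_of` also exposes the plain
deduplicated pair set, and :func:`fisher_enrichment` accepts either
counts (multisets) or plain pair collections.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .state_space import StateSpace, enumerate_coefficients

__all__ = [
    "ContactSet",
    "EnrichmentResult",
    "all_position_pairs",
    "position_pairs_of",
    "pair_occurrences",
    "background_pair_occurrences",
    "fisher_enrichment",
    "random_model_null",
    "model_enrichment",
]

Pair = tuple[int, int]


def _norm_pair(a: int, b: int) -> Pair:
    if a == b:
        raise ValueError(f"self-pair ({a}, {b}) is not a position pair")
    return (min(int(a), int(b)), max(int(a), int(b)))


@dataclass(frozen=True)
class ContactSet:
    """Unordered physically interacting position pairs (1-based)."""

    physical_pairs: frozenset[Pair]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], n_positions: int | None = None) -> "ContactSet":
        norm = {_norm_pair(a, b) for a, b in pairs}
        if n_positions is not None:
            bad = [p for p in norm if p[1] > n_positions or p[0] < 1]
            if bad:
                raise ValueError(f"contact pairs outside positions 1..{n_positions}: {bad}")
        return cls(frozenset(norm))


@dataclass
class EnrichmentResult:
    """2x2 contingency table with odds ratio and two-sided p-value.

    Table layout: rows = pair observed / not observed among model
    coefficients, columns = pair is / is not a physical contact.  The
    odds ratio is the cross-product ratio; when a cell is zero a
    Haldane correction (+0.5 to every cell) is applied to the odds
    ratio only and flagged.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    haldane_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "haldane_corrected": self.haldane_corrected,
        }


def all_position_pairs(space: StateSpace) -> set[Pair]:
    """Background set: every unordered pair of positions."""
    return set(itertools.combinations(range(1, space.n_positions + 1), 2))


def position_pairs_of(nonzero_ids: Iterable) -> set[Pair]:
    """Unique position pairs implicated by coefficients of order >= 2.

    A coefficient with k >= 2 mutated positions contributes all C(k, 2)
    pairs among them; pairs are counted once however many coefficients
    contain them.
    """
    pairs: set[Pair] = set()
    for states in nonzero_ids:
        mutated = [k + 1 for k, a in enumerate(states) if a != 0]
        pairs.update(itertools.combinations(mutated, 2))
    return pairs


def pair_occurrences(ids: Iterable) -> Counter:
    """Position-pair occurrence counts over coefficients of order >= 2.

    Each coefficient with ``k >= 2`` mutated positions contributes one
    occurrence of each of its ``C(k, 2)`` pairs; a pair recurring in
    many coefficients accumulates multiplicity.
    """
    counts: Counter = Counter()
    for states in ids:
        mutated = [k + 1 for k, a in enumerate(states) if a != 0]
        if len(mutated) >= 2:
            counts.update(itertools.combinations(mutated, 2))
    return counts


def background_pair_occurrences(space: StateSpace, max_order: int) -> Counter:
    """Pair occurrences across *all possible* coefficients of order <=
    ``max_order`` — the enrichment background."""
    return pair_occurrences(enumerate_coefficients(space, max_order))


def _as_counts(pairs) -> Counter:
    if isinstance(pairs, Mapping):
        return Counter({_norm_pair(*p): int(v) for p, v in pairs.items() if v})
    return Counter({_norm_pair(*p): 1 for p in pairs})


def fisher_enrichment(
    observed_pairs,
    contacts: ContactSet,
    background_pairs,
) -> EnrichmentResult:
    """Fisher's exact test of contact enrichment among observed pairs.

    ``observed_pairs`` and ``background_pairs`` may be plain pair
    collections (each pair counted once) or pair -> count mappings
    (occurrence multisets); observed counts must nowhere exceed the
    background counts.
    """
    background = _as_counts(background_pairs)
    if not background:
        raise ValueError("background pair set is empty")
    observed = _as_counts(observed_pairs)
    if any(observed[p] > background[p] for p in observed):
        raise ValueError("observed pairs must be a subset of the background")
    contact = set(contacts.physical_pairs)
    if not contact <= set(background):
        raise ValueError("contact pairs must be a subset of the background")

    a = sum(v for p, v in observed.items() if p in contact)
    b = sum(v for p, v in observed.items() if p not in contact)
    c = sum(v for p, v in background.items() if p in contact) - a
    d = sum(v for p, v in background.items() if p not in contact) - b
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    return EnrichmentResult(table, float(odds), float(p), corrected)


def random_model_null(
    counts_per_order: Mapping[int, int],
    space: StateSpace,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, ...]]:
    """Random coefficient ids matching a model's order distribution.

    For each order, ids are drawn uniformly without replacement from
    all coefficient ids of that order; used to check that the Fisher
    null behaves (random models are not enriched).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vectors = space.all_genotypes()
    orders = (vectors != 0).sum(axis=1)
    out: list[tuple[int, ...]] = []
    for order in sorted(counts_per_order):
        count = counts_per_order[order]
        pool = np.nonzero(orders == order)[0]
        if count < 0 or count > len(pool):
            raise ValueError(
                f"cannot draw {count} ids of order {order}: only "
                f"{len(pool)} exist"
            )
        chosen = rng.choice(pool, size=count, replace=False)
        out.extend(tuple(int(x) for x in vectors[i]) for i in chosen)
    return out


def model_enrichment(summary, contacts: ContactSet) -> list[EnrichmentResult]:
    """Per-model contact enrichment for a repeated-fit summary.

    For every fitted model, the pairs of its non-zero coefficients of
    order >= 2 (with multiplicity) are tested against the occurrence
    background of all possible coefficients up to the summary's
    ``max_order``.
    """
    background = background_pair_occurrences(summary.space, summary.max_order)
    results = []
    for fit in summary.fits:
        ids = summary.coefficient_vectors[fit.coef != 0]
        results.append(
            fisher_enrichment(pair_occurrences(ids), contacts, background)
        )
    return results
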