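"""The extended Walsh-Hadamard transform and its inverse.

For a landscape over positions with state counts ``(s_1, ..., s_n)`` the
transform ``H`` decomposes the phenotype vector into background-averaged
epistatic coefficients together with a diagonal weighting matrix ``V``
(``eps = V @ H @ y``).  For biallelic landscapes (all ``s_k = 2``) ``H``
is the canonical Walsh-Hadamard matrix; for more states per position it
acquires zero entries that exclude genotypes which are neither relevant
intermediates nor alternative backgrounds for a given coefficient.

``A = H^{-1}`` has its own recursion, and every entry of ``H``, ``A``,
``V`` and ``V^{-1}`` has a closed form in terms of the two state vectors
it compares, so sub-matrices can be extracted without ever materializing
a full matrix.  The product ``A @ V^{-1}`` is the sequence-feature
embedding used for regression (``y = A @ V^{-1} @ eps``).

Full dense constructions are exact: ``H`` entries are the integers
{-1, 0, 1}; ``A`` is built as an integer numerator matrix divided by
``prod(s_k)`` at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import prod
from typing import Literal, Sequence

import numpy as np

from .state_space import StateSpace, vectors_of

__all__ = [
    "TransformMatrix",
    "build_H",
    "build_V",
    "build_Vinv",
    "build_A",
    "element_H",
    "element_A",
    "element_V",
    "element_Vinv",
    "feature_matrix",
    "DEFAULT_SIZE_CAP",
    "DEFAULT_CHUNK_ROWS",
]

#: Dense builders refuse spaces with more genotypes than this by default;
#: larger problems should use the element-wise / chunked APIs.
DEFAULT_SIZE_CAP = 4096

#: Default number of rows per batch in chunked feature construction.
DEFAULT_CHUNK_ROWS = 1024

MatrixKind = Literal["H", "V", "Vinv", "A", "Feature"]


@dataclass(frozen=True)
class TransformMatrix:
    """A dense transform (sub-)matrix with its rank labels.

    ``row_ids`` / ``col_ids`` are 1-based genotype/coefficient ranks, so
    sub-matrices stay unambiguous.
    """

    kind: MatrixKind
    space: StateSpace
    values: np.ndarray
    row_ids: np.ndarray
    col_ids: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __matmul__(self, other):
        if isinstance(other, TransformMatrix):
            return self.values @ other.values
        return self.values @ other


def _check_cap(space: StateSpace, size_cap: int) -> None:
    if space.total_size > size_cap:
        raise ValueError(
            f"space has {space.total_size} genotypes, above the dense-matrix "
            f"cap of {size_cap}; use the element_*/feature_matrix APIs or "
            "raise size_cap explicitly"
        )


def _full_ids(space: StateSpace) -> np.ndarray:
    return np.arange(1, space.total_size + 1)


def _h1(s: int) -> np.ndarray:
    """Single-position transform: first row/column ones, -1 diagonal."""
    m = np.zeros((s, s), dtype=np.int64)
    m[0, :] = 1
    m[:, 0] = 1
    m[np.arange(1, s), np.arange(1, s)] = -1
    return m


def _a1_numerator(s: int) -> np.ndarray:
    """Numerator of the single-position inverse: A_1 = numerator / s."""
    m = np.ones((s, s), dtype=np.int64)
    m[np.arange(1, s), np.arange(1, s)] = 1 - s
    return m


def _v1_diag(s: int) -> list[Fraction]:
    return [Fraction(1, s)] + [Fraction(-1)] * (s - 1)


def build_H(space: StateSpace, size_cap: int = DEFAULT_SIZE_CAP) -> TransformMatrix:
    """Dense extended Walsh-Hadamard matrix by block recursion.

    ``H`` for ``n+1`` positions is a block matrix over the states of the
    *first* (most significant) position: first block-row all ``+H_n``,
    then ``H_n`` in the first block-column with ``-H_n`` on the block
    diagonal and zeros elsewhere.  ``H_0 = [1]``.
    """
    _check_cap(space, size_cap)

    def rec(counts: tuple[int, ...]) -> np.ndarray:
        if not counts:
            return np.array([[1]], dtype=np.int64)
        inner = rec(counts[1:])
        s, m = counts[0], inner.shape[0]
        out = np.zeros((s * m, s * m), dtype=np.int64)
        out[:m, :] = np.tile(inner, s)
        for b in range(1, s):
            out[b * m : (b + 1) * m, :m] = inner
            out[b * m : (b + 1) * m, b * m : (b + 1) * m] = -inner
        return out

    vals = rec(space.state_counts)
    ids = _full_ids(space)
    return TransformMatrix("H", space, vals, ids, ids)


def build_A(space: StateSpace, size_cap: int = DEFAULT_SIZE_CAP) -> TransformMatrix:
    """Dense inverse transform ``A = H^{-1}`` by block recursion.

    Adding a position with ``s`` states maps ``A_n`` to a block matrix
    ``(1/s) * [[A, A, ...], [A, (1-s)A, A, ...], ...]`` with ``(1-s)A``
    on the block diagonal below the first block-row.  The integer
    numerator is accumulated exactly and divided by ``prod(s_k)`` once.
    """
    _check_cap(space, size_cap)

    def rec(counts: tuple[int, ...]) -> np.ndarray:
        if not counts:
            return np.array([[1]], dtype=np.int64)
        inner = rec(counts[1:])
        s, m = counts[0], inner.shape[0]
        out = np.tile(inner, (s, s))
        for b in range(1, s):
            out[b * m : (b + 1) * m, b * m : (b + 1) * m] = (1 - s) * inner
        return out

    vals = rec(space.state_counts) / prod(space.state_counts)
    ids = _full_ids(space)
    return TransformMatrix("A", space, vals, ids, ids)


def _build_v(space: StateSpace, inverse: bool, size_cap: int) -> TransformMatrix:
    _check_cap(space, size_cap)
    diag = [Fraction(1)]
    for s in space.state_counts:
        diag = [d * v for d in diag for v in _v1_diag(s)]
    if inverse:
        diag = [1 / d for d in diag]
    vals = np.diag(np.array([float(d) for d in diag]))
    ids = _full_ids(space)
    return TransformMatrix("Vinv" if inverse else "V", space, vals, ids, ids)


def build_V(space: StateSpace, size_cap: int = DEFAULT_SIZE_CAP) -> TransformMatrix:
    """Dense diagonal weighting matrix ``V`` (recursion: ``(1/s)V`` then
    ``-V`` blocks on the diagonal)."""
    return _build_v(space, inverse=False, size_cap=size_cap)


def build_Vinv(space: StateSpace, size_cap: int = DEFAULT_SIZE_CAP) -> TransformMatrix:
    """Dense inverse weighting matrix ``V^{-1}``."""
    return _build_v(space, inverse=True, size_cap=size_cap)


# ---------------------------------------------------------------------------
# Element formulas: any entry from the two state vectors alone.
# ---------------------------------------------------------------------------


def _vec(rank: int, space: StateSpace) -> np.ndarray:
    return vectors_of(np.array([rank]), space)[0]


def element_H(i: int, j: int, space: StateSpace) -> int:
    """Entry ``(i, j)`` of ``H`` (1-based ranks), in {-1, 0, 1}.

    With ``E`` = number of positions where both vectors carry the same
    mutated allele and ``M`` = ``E`` plus the number of positions where
    either carries wild-type: ``(-1)**E`` if ``M = n`` else 0.
    """
    gi, gj = _vec(i, space), _vec(j, space)
    same_mut = (gi == gj) & (gi != 0)
    e = int(same_mut.sum())
    m = e + int(((gi == 0) | (gj == 0)).sum())
    return (-1) ** e if m == space.n_positions else 0


def element_A(i: int, j: int, space: StateSpace) -> float:
    """Entry ``(i, j)`` of ``A``: ``prod_k (1-s_k)^{e_k} / prod_k s_k``
    with ``e_k = 1`` iff both vectors share the same mutated allele at
    position ``k``."""
    gi, gj = _vec(i, space), _vec(j, space)
    num = 1
    for a, b, s in zip(gi, gj, space.state_counts):
        if a == b and a != 0:
            num *= 1 - s
    return num / prod(space.state_counts)


def element_V(i: int, space: StateSpace) -> float:
    """Diagonal entry ``(i, i)`` of ``V``:
    ``(-1)^{n-W} prod_k (1/s_k)^{w_k}`` where ``w_k`` indicates
    wild-type at position ``k`` and ``W = sum w_k``."""
    gi = _vec(i, space)
    val = Fraction(1)
    for a, s in zip(gi, space.state_counts):
        val *= Fraction(1, s) if a == 0 else Fraction(-1)
    return float(val)


def element_Vinv(i: int, space: StateSpace) -> float:
    """Diagonal entry of ``V^{-1}``: ``(-1)^{n-W} prod_k s_k^{w_k}``."""
    gi = _vec(i, space)
    val = 1
    for a, s in zip(gi, space.state_counts):
        val *= s if a == 0 else -1
    return float(val)


# ---------------------------------------------------------------------------
# Feature sub-matrix A @ Vinv, chunked.
# ---------------------------------------------------------------------------


def feature_values(
    genotypes: np.ndarray, coefficients: np.ndarray, space: StateSpace
) -> np.ndarray:
    """Feature block for genotype rows and coefficient columns.

    Entry ``(g, c) = A[g, c] * Vinv[c, c]``; per position this collapses
    to ``1`` when the coefficient averages the position (state 0),
    ``(s_k - 1)/s_k`` when the genotype carries the coefficient's
    mutated allele, and ``-1/s_k`` otherwise.

    Parameters are ``(m, n)`` and ``(p, n)`` state-vector arrays; the
    result is ``(m, p)`` float64.
    """
    g = np.asarray(genotypes)[:, None, :]
    c = np.asarray(coefficients)[None, :, :]
    s = np.asarray(space.state_counts)[None, None, :]
    factors = np.where(c == 0, 1.0, np.where(g == c, (s - 1) / s, -1.0 / s))
    return factors.prod(axis=2)


def feature_matrix(
    genotype_ranks: Sequence[int],
    coefficient_ranks: Sequence[int],
    space: StateSpace,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> TransformMatrix:
    """Sub-matrix of ``A @ V^{-1}`` for given rank lists, built in row
    batches of ``chunk_rows`` so arbitrarily many rows never require the
    full dense matrices."""
    rows = np.asarray(list(genotype_ranks), dtype=np.int64)
    cols = np.asarray(list(coefficient_ranks), dtype=np.int64)
    cvec = vectors_of(cols, space) if cols.size else np.empty((0, space.n_positions), int)
    blocks = []
    for start in range(0, len(rows), chunk_rows):
        gvec = vectors_of(rows[start : start + chunk_rows], space)
        blocks.append(feature_values(gvec, cvec, space))
    vals = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.empty((0, len(cols)))
    )
    if cols.size == 0:
        vals = vals.reshape(len(rows), 0)
    return TransformMatrix("Feature", space, vals, rows, cols)
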