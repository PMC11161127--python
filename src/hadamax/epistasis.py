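"""Decomposition of complete landscapes into background-averaged epistasis.

A complete landscape assigns a phenotype score to every genotype of its
state space.  The decomposition ``eps = V @ H @ y`` yields one epistatic
coefficient per genotype index: the zeroth-order term (wild-type rank 1)
is the mean phenotype over all genotypes, first-order terms are single
mutant effects relative to wild-type, and order-k terms quantify how far
a k-fold mutation combination deviates from additivity, averaged over
all genetic backgrounds at the remaining positions.

Because both ``V @ H`` and its inverse ``A @ V^{-1}`` factor into one
small matrix per sequence position, the forward and inverse transforms
are applied axis-by-axis on the phenotype tensor (shape ``(s_1, ...,
s_n)``) rather than through dense ``prod(s_k)``-sized matrices; complete
landscapes far above the dense-matrix cap remain tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .state_space import StateSpace
from .transforms import _a1_numerator, _h1, _v1_diag

__all__ = [
    "Landscape",
    "CoefficientSet",
    "decompose",
    "reconstruct",
    "propagate_errors",
    "impute_missing",
]


@dataclass
class Landscape:
    """Phenotype scores (and optional standard errors) per genotype rank.

    ``phenotype`` and ``error`` map 1-based ranks to values; the
    landscape is *complete* when every rank of the space is present.
    """

    space: StateSpace
    phenotype: dict[int, float]
    error: dict[int, float] | None = None
    imputed_ranks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        size = self.space.total_size
        for r in self.phenotype:
            if not 1 <= r <= size:
                raise ValueError(f"rank {r} out of range [1, {size}]")
        if self.error is not None:
            for r, e in self.error.items():
                if r not in self.phenotype:
                    raise ValueError(f"error given for unmeasured rank {r}")
                if e < 0:
                    raise ValueError(f"negative error {e} at rank {r}")

    @property
    def complete(self) -> bool:
        return len(self.phenotype) == self.space.total_size

    @property
    def n_observed(self) -> int:
        return len(self.phenotype)

    def phenotype_vector(self) -> np.ndarray:
        """Phenotypes in rank order; requires completeness."""
        self._require_complete()
        return self._vector(self.phenotype)

    def error_vector(self) -> np.ndarray:
        self._require_complete()
        if self.error is None or len(self.error) != self.space.total_size:
            raise ValueError("landscape has no complete error column")
        return self._vector(self.error)

    def observed_ranks(self) -> np.ndarray:
        return np.array(sorted(self.phenotype), dtype=np.int64)

    def _vector(self, mapping: Mapping[int, float]) -> np.ndarray:
        out = np.empty(self.space.total_size)
        for r, v in mapping.items():
            out[r - 1] = v
        return out

    def _require_complete(self) -> None:
        if not self.complete:
            missing = self.space.total_size - len(self.phenotype)
            raise ValueError(
                f"landscape is incomplete ({missing} of "
                f"{self.space.total_size} genotypes missing); impute "
                "phenotypes (impute_missing) or infer coefficients by "
                "regression instead"
            )

    @classmethod
    def from_vector(
        cls, space: StateSpace, y: np.ndarray, err: np.ndarray | None = None
    ) -> "Landscape":
        phen = {r + 1: float(v) for r, v in enumerate(np.asarray(y, float))}
        errs = (
            {r + 1: float(v) for r, v in enumerate(np.asarray(err, float))}
            if err is not None
            else None
        )
        return cls(space, phen, errs)


@dataclass
class CoefficientSet:
    """Background-averaged epistatic coefficients, indexed like genotypes.

    Rank 1 holds the zeroth-order term; the order of any other rank is
    the number of nonzero entries of its state vector.
    """

    space: StateSpace
    value: np.ndarray
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (self.space.total_size,):
            raise ValueError(
                f"expected {self.space.total_size} coefficients, "
                f"got shape {self.value.shape}"
            )
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.value.shape:
                raise ValueError("error vector shape mismatch")

    def __getitem__(self, rank: int) -> float:
        return float(self.value[rank - 1])

    def orders(self) -> np.ndarray:
        return (self.space.all_genotypes() != 0).sum(axis=1)


def _apply_per_position(y: np.ndarray, space: StateSpace, mats) -> np.ndarray:
    """Apply one matrix per position along the matching tensor axis."""
    t = np.asarray(y, dtype=float).reshape(space.state_counts)
    for axis, m in enumerate(mats):
        t = np.moveaxis(np.tensordot(m, t, axes=(1, axis)), 0, axis)
    return t.reshape(-1)


def _vh_factors(space: StateSpace) -> list[np.ndarray]:
    return [
        np.array([[float(v) for v in _v1_diag(s)]]).T * _h1(s)
        for s in space.state_counts
    ]


def _avinv_factors(space: StateSpace) -> list[np.ndarray]:
    out = []
    for s in space.state_counts:
        vinv = np.array([1.0 / float(v) for v in _v1_diag(s)])
        out.append(_a1_numerator(s) / s * vinv[None, :])
    return out


def decompose(land: Landscape) -> CoefficientSet:
    """``eps = V @ H @ y`` for a complete landscape.

    Errors, when present for every genotype, are propagated alongside
    (see :func:`propagate_errors`).
    """
    y = land.phenotype_vector()
    eps = _apply_per_position(y, land.space, _vh_factors(land.space))
    err = None
    if land.error is not None and len(land.error) == land.space.total_size:
        err = propagate_errors(land).error
    return CoefficientSet(land.space, eps, err)


def reconstruct(coeffs: CoefficientSet) -> Landscape:
    """``y = A @ V^{-1} @ eps``, the exact inverse of :func:`decompose`."""
    y = _apply_per_position(coeffs.value, coeffs.space, _avinv_factors(coeffs.space))
    return Landscape.from_vector(coeffs.space, y)


def propagate_errors(land: Landscape) -> CoefficientSet:
    """First-order error propagation through the decomposition.

    Treating per-genotype measurement errors as independent,
    ``sigma_eps_i = sqrt( sum_j ((V H)_ij sigma_y_j)^2 )``.  The squared
    weight matrix factors per position exactly like ``V H`` itself, so
    the coefficient variances are a per-axis transform of the squared
    error tensor.
    """
    sigma = land.error_vector()
    sq_factors = [m**2 for m in _vh_factors(land.space)]
    var = _apply_per_position(sigma**2, land.space, sq_factors)
    eps = _apply_per_position(land.phenotype_vector(), land.space, _vh_factors(land.space))
    return CoefficientSet(land.space, eps, np.sqrt(var))


def impute_missing(land: Landscape) -> Landscape:
    """Fill unmeasured genotypes with the mean phenotype at their
    mutation order (number of mutated positions).

    Raises if some missing genotype's order has no observed genotype at
    all.  Imputed ranks are flagged on the returned landscape; imputed
    genotypes carry no measurement error.
    """
    if land.complete:
        return land
    orders = (land.space.all_genotypes() != 0).sum(axis=1)
    observed = np.zeros(land.space.total_size, dtype=bool)
    observed[[r - 1 for r in land.phenotype]] = True
    values = np.zeros(land.space.total_size)
    values[observed] = [land.phenotype[r + 1] for r in np.nonzero(observed)[0]]

    missing_orders = sorted(set(orders[~observed].tolist()))
    empty = [o for o in missing_orders if not observed[orders == o].any()]
    if empty:
        raise ValueError(
            "cannot impute: no observed genotypes at mutation order(s) "
            f"{empty}"
        )
    phen = dict(land.phenotype)
    imputed = set(land.imputed_ranks)
    for o in missing_orders:
        mean = values[observed & (orders == o)].mean()
        for idx in np.nonzero(~observed & (orders == o))[0]:
            phen[int(idx) + 1] = float(mean)
            imputed.add(int(idx) + 1)
    return Landscape(land.space, phen, land.error, frozenset(imputed))
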