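"""Sparse inference of epistatic coefficients from incomplete landscapes.

When only a subset of a combinatorially complete landscape has measured
phenotypes, coefficients are estimated by L1-penalized regression of
phenotype on sequence features.  Two embeddings are supported:

``background_averaged``
    Rows of ``A @ V^{-1}`` restricted to coefficient columns up to a
    chosen order — the inverse-transform feature matrix, so the fitted
    weights are background-averaged epistatic coefficients.
``one_hot``
    Indicator features: a column is 1 when the genotype carries exactly
    the column's mutated allele(s) at the named position(s).  Fitted
    weights are background-relative ("biochemical") coefficients.

The regularization parameter is selected by repeated k-fold
cross-validation over a log-spaced grid, and model statistics are
summarized over many models fit to independent random training subsets:
a coefficient is called non-zero when its interquartile range across
models excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import RepeatedKFold

from .epistasis import Landscape
from .state_space import StateSpace, enumerate_coefficients, ranks_of, vectors_of
from .transforms import feature_values

__all__ = [
    "FitConfig",
    "ModelSummary",
    "build_features",
    "fit_sparse_model",
    "repeated_fits",
    "variance_explained",
]

Encoding = Literal["background_averaged", "one_hot"]


@dataclass
class FitConfig:
    """Settings for sparse model fitting.

    ``train_fraction`` is the fraction of available (measured) variants
    sampled without replacement as each model's training set; the
    remainder is that model's test set.  ``lambda_range`` bounds the L1
    penalty grid (scikit-learn's ``alpha``).
    """

    encoding: Encoding = "background_averaged"
    max_order: int = 3
    lambda_range: tuple[float, float] = (0.005, 0.25)
    lambda_grid_size: int = 50
    cv_folds: int = 10
    cv_repeats: int = 3
    n_models: int = 100
    train_fraction: float = 0.64
    standardize: bool = False
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        lo, hi = self.lambda_range
        if not 0 < lo < hi:
            raise ValueError("lambda_range must satisfy 0 < lo < hi")
        if self.encoding not in ("background_averaged", "one_hot"):
            raise ValueError(f"unknown encoding {self.encoding!r}")

    def lambda_grid(self) -> np.ndarray:
        lo, hi = self.lambda_range
        return np.logspace(np.log10(lo), np.log10(hi), self.lambda_grid_size)

    def to_dict(self) -> dict:
        return {
            "encoding": self.encoding,
            "max_order": self.max_order,
            "lambda_range": list(self.lambda_range),
            "lambda_grid_size": self.lambda_grid_size,
            "cv_folds": self.cv_folds,
            "cv_repeats": self.cv_repeats,
            "n_models": self.n_models,
            "train_fraction": self.train_fraction,
            "standardize": self.standardize,
            "max_iter": self.max_iter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        kwargs = dict(d)
        if "lambda_range" in kwargs:
            kwargs["lambda_range"] = tuple(kwargs["lambda_range"])
        return cls(**kwargs)


@dataclass
class SingleFit:
    """One fitted sparse model."""

    intercept: float
    coef: np.ndarray
    chosen_lambda: float
    train_ranks: np.ndarray
    test_r2: float | None
    test_r2_of_max: float | None
    degenerate: bool = False


@dataclass
class ModelSummary:
    """Median/IQR statistics over repeated sparse fits.

    ``table`` has one row per coefficient column (plus the zeroth-order
    intercept row, rank 1) with columns ``rank``, ``states``, ``order``,
    ``median``, ``q25``, ``q75``, ``nonzero``; a coefficient is flagged
    non-zero when [q25, q75] excludes zero.
    """

    space: StateSpace
    encoding: Encoding
    max_order: int
    table: pd.DataFrame
    #: (p, n) state vectors aligned with every fit's ``coef`` entries
    coefficient_vectors: np.ndarray
    fits: list[SingleFit]
    test_r2_median: float
    test_r2_iqr: tuple[float, float]
    r2_of_max_median: float | None
    lambdas: np.ndarray

    def nonzero_ranks(self) -> np.ndarray:
        t = self.table
        return t.loc[t["nonzero"], "rank"].to_numpy()


def build_features(
    genotype_ranks: Sequence[int],
    space: StateSpace,
    max_order: int,
    encoding: Encoding = "background_averaged",
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix for the given genotypes and all coefficient columns
    of order 1..``max_order`` (the zeroth-order column is the intercept
    and is excluded).

    Returns ``(X, coefficient_vectors)`` where ``coefficient_vectors``
    is the ``(p, n)`` array of column ids in rank order.
    """
    cvecs = enumerate_coefficients(space, max_order)
    cvecs = cvecs[(cvecs != 0).any(axis=1)]  # drop the zeroth-order id
    gvecs = vectors_of(np.asarray(list(genotype_ranks), dtype=np.int64), space)
    if encoding == "background_averaged":
        X = feature_values(gvecs, cvecs, space)
    elif encoding == "one_hot":
        g = gvecs[:, None, :]
        c = cvecs[None, :, :]
        X = ((c == 0) | (g == c)).all(axis=2).astype(float)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return X, cvecs


def fit_sparse_model(
    X: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float]:
    """L1 fit with cross-validated penalty selection.

    Returns ``(coef, intercept, chosen_lambda)``.  The intercept is
    unpenalized and corresponds to the zeroth-order coefficient.  A
    zero-variance response short-circuits to an intercept-only model.
    """
    y = np.asarray(y, float)
    if len(y) != X.shape[0]:
        raise ValueError("feature rows and response length differ")
    if len(y) < config.cv_folds:
        raise ValueError(
            f"{len(y)} training rows < cv_folds={config.cv_folds}"
        )
    if np.ptp(y) == 0:
        return np.zeros(X.shape[1]), float(y[0]) if len(y) else 0.0, float("nan")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cv = RepeatedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=int(rng.integers(2**31 - 1)),
    )
    if config.standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = X / scale
    else:
        scale = None
        Xs = X
    model = LassoCV(
        alphas=config.lambda_grid(),
        cv=cv,
        fit_intercept=True,
        max_iter=config.max_iter,
    ).fit(Xs, y)
    coef = model.coef_ / scale if scale is not None else model.coef_
    return coef, float(model.intercept_), float(model.alpha_)


def variance_explained(
    predictions: np.ndarray,
    y_test: np.ndarray,
    technical_variance: float = 0.0,
) -> tuple[float, float]:
    """Raw test-set R² and its fraction of the maximum explainable.

    The maximum explainable variance fraction is ``1 - technical_variance
    / var(y_test)``: total phenotypic variance minus known measurement
    variance sets the ceiling for any model.
    """
    y_test = np.asarray(y_test, float)
    predictions = np.asarray(predictions, float)
    if len(y_test) != len(predictions):
        raise ValueError("prediction and response lengths differ")
    total = float(np.var(y_test))
    if total == 0:
        raise ValueError("zero total variance in test responses")
    r2 = 1.0 - float(np.mean((y_test - predictions) ** 2)) / total
    max_frac = 1.0 - technical_variance / total
    r2_of_max = r2 / max_frac if max_frac > 0 else float("nan")
    return r2, r2_of_max


def repeated_fits(land: Landscape, config: FitConfig) -> ModelSummary:
    """Fit ``n_models`` sparse models to random training subsets.

    Each model draws ``train_fraction`` of the measured variants
    without replacement (per-model seed spawned from the master seed, so
    any single model is reproducible in isolation); the held-out
    measured variants form its test set.  Per-coefficient medians and
    interquartile ranges are taken across models, and the non-zero set
    is defined by the IQR-excludes-zero rule.
    """
    ranks = land.observed_ranks()
    n_train = max(1, round(config.train_fraction * len(ranks)))
    if n_train < config.cv_folds:
        raise ValueError(
            f"training set of {n_train} variants is smaller than "
            f"cv_folds={config.cv_folds}"
        )
    X_all, cvecs = build_features(ranks, land.space, config.max_order, config.encoding)
    y_all = np.array([land.phenotype[r] for r in ranks])
    tech_var = None
    if land.error is not None and len(land.error) == len(ranks):
        tech_var = float(np.mean([land.error[r] ** 2 for r in ranks]))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_models)
    fits: list[SingleFit] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        train_idx = rng.choice(len(ranks), n_train, replace=False)
        test_mask = np.ones(len(ranks), bool)
        test_mask[train_idx] = False
        coef, intercept, lam = fit_sparse_model(
            X_all[train_idx], y_all[train_idx], config, rng=rng
        )
        r2 = r2max = None
        if test_mask.any() and np.ptp(y_all[test_mask]) > 0:
            pred = X_all[test_mask] @ coef + intercept
            r2, r2max = variance_explained(
                pred, y_all[test_mask], tech_var if tech_var is not None else 0.0
            )
        fits.append(
            SingleFit(
                intercept=intercept,
                coef=coef,
                chosen_lambda=lam,
                train_ranks=ranks[train_idx],
                test_r2=r2,
                test_r2_of_max=r2max if tech_var is not None else None,
                degenerate=np.isnan(lam),
            )
        )

    coef_stack = np.stack([f.coef for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    # prepend the zeroth-order (intercept) row at rank 1
    full_stack = np.concatenate([intercepts[:, None], coef_stack], axis=1)
    zero_vec = np.zeros((1, land.space.n_positions), dtype=cvecs.dtype)
    all_vecs = np.concatenate([zero_vec, cvecs], axis=0)
    q25, med, q75 = np.percentile(full_stack, [25, 50, 75], axis=0)
    nonzero = (q25 > 0) | (q75 < 0)
    table = pd.DataFrame(
        {
            "rank": ranks_of(all_vecs, land.space),
            "states": [",".join(map(str, v)) for v in all_vecs],
            "order": (all_vecs != 0).sum(axis=1),
            "median": med,
            "q25": q25,
            "q75": q75,
            "nonzero": nonzero,
        }
    )
    r2s = np.array([f.test_r2 for f in fits if f.test_r2 is not None])
    r2maxs = np.array([f.test_r2_of_max for f in fits if f.test_r2_of_max is not None])
    if r2s.size == 0:
        r2_med, r2_iqr = float("nan"), (float("nan"), float("nan"))
    else:
        r2_med = float(np.median(r2s))
        r2_iqr = (float(np.percentile(r2s, 25)), float(np.percentile(r2s, 75)))
    return ModelSummary(
        space=land.space,
        encoding=config.encoding,
        max_order=config.max_order,
        table=table,
        coefficient_vectors=cvecs,
        fits=fits,
        test_r2_median=r2_med,
        test_r2_iqr=r2_iqr,
        r2_of_max_median=float(np.median(r2maxs)) if r2maxs.size else None,
        lambdas=np.array([f.chosen_lambda for f in fits]),
    )
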