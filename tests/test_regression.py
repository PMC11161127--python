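import numpy as np
import pytest

from hadamax import (
    FitConfig,
    Landscape,
    SimulationConfig,
    StateSpace,
    build_A,
    build_Vinv,
    build_features,
    enumerate_coefficients,
    fit_sparse_model,
    repeated_fits,
    simulate_landscape,
    variance_explained,
)
from hadamax.state_space import ranks_of


@pytest.fixture(scope="module")
def small_noisy_landscape():
    """Complete 3^3 landscape with one interacting pair and mild noise."""
    cfg = SimulationConfig(
        space=StateSpace((3, 3, 3)),
        interacting_pairs=((1, 3),),
        noise_sd=0.3,
        seed=8,
    )
    return simulate_landscape(cfg)


class TestBuildFeatures:
    def test_one_hot_indicator_semantics(self):
        space = StateSpace((3, 3))
        X, cvecs = build_features([4 + 1 * 0 + 0, 1], space, 2, "one_hot")
        # genotype (1,2) has rank 1 + 1*3 + 2 = 6
        X, cvecs = build_features([6], space, 2, "one_hot")
        cols = {tuple(v): i for i, v in enumerate(cvecs)}
        assert X[0, cols[(1, 0)]] == 1.0  # carries allele 1 at position 1
        assert X[0, cols[(2, 0)]] == 0.0  # wrong allele
        assert X[0, cols[(1, 2)]] == 1.0  # carries the full combination
        assert X[0, cols[(1, 1)]] == 0.0

    def test_background_averaged_matches_dense_restriction(self):
        space = StateSpace((3, 3))
        X, cvecs = build_features(range(1, 10), space, 2, "background_averaged")
        dense = build_A(space).values @ build_Vinv(space).values
        cols = ranks_of(cvecs, space) - 1
        assert np.abs(X - dense[:, cols]).max() < 1e-12

    def test_zeroth_column_is_excluded(self):
        space = StateSpace((3, 3))
        X, cvecs = build_features([1, 2], space, 2)
        assert not (cvecs == 0).all(axis=1).any()
        assert X.shape[1] == 8  # 9 ids minus the zeroth

    def test_both_full_order_embeddings_are_bases(self, small_space):
        """Either embedding plus an intercept spans any complete
        landscape exactly (full-rank bases of the same space)."""
        rng = np.random.default_rng(17)
        y = rng.normal(size=small_space.total_size)
        for enc in ("background_averaged", "one_hot"):
            X, _ = build_features(
                range(1, small_space.total_size + 1),
                small_space,
                small_space.n_positions,
                enc,
            )
            Xi = np.column_stack([np.ones(len(y)), X])
            resid = np.linalg.lstsq(Xi, y, rcond=None)[1]
            fitted = Xi @ np.linalg.lstsq(Xi, y, rcond=None)[0]
            assert np.abs(fitted - y).max() < 1e-8


class TestFitSparseModel:
    def test_noise_free_full_landscape_recovery_at_small_lambda(self):
        """On the complete noise-free landscape the L1 fit keeps every
        true term and recovers it up to the analytic shrinkage bound.

        Feature columns of the same position group are correlated
        (per shared position by -1/3), so a group of g correlated
        columns can shrink by up to g*lambda/Var(column); as
        lambda -> 0 the recovery is exact."""
        cfg = SimulationConfig(seed=6, noise_sd=0)
        sim = simulate_landscape(cfg)
        ranks = np.arange(1, 4097)
        X, cvecs = build_features(ranks, sim.landscape.space, 2)
        y = sim.landscape.phenotype_vector()
        from sklearn.linear_model import Lasso

        truth = sim.truth.value[ranks_of(cvecs, sim.landscape.space) - 1]
        nz_truth = truth != 0
        col_var = X.var(axis=0)
        group = np.where((cvecs != 0).sum(axis=1) == 1, 3, 9)

        m = Lasso(alpha=0.005, max_iter=20000).fit(X, y)
        err = np.abs(m.coef_ - truth)
        bound = group * 0.005 / col_var + 1e-3
        assert (err[nz_truth] <= bound[nz_truth]).all()

        tiny = Lasso(alpha=1e-6, max_iter=200000, tol=1e-10).fit(X, y)
        assert np.abs(tiny.coef_ - truth).max() < 1e-3

    def test_constant_response_returns_intercept_only(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        coef, intercept, lam = fit_sparse_model(
            X, np.full(20, 1.5), FitConfig(cv_folds=5)
        )
        assert (coef == 0).all()
        assert intercept == 1.5
        assert np.isnan(lam)

    def test_permuted_response_explains_nothing(self, small_noisy_landscape):
        land = small_noisy_landscape.landscape
        ranks = land.observed_ranks()
        X, _ = build_features(ranks, land.space, 2)
        rng = np.random.default_rng(3)
        y = rng.permutation(land.phenotype_vector())
        train = rng.choice(len(y), 20, replace=False)
        test = np.setdiff1d(np.arange(len(y)), train)
        cfg = FitConfig(cv_folds=5, cv_repeats=1, seed=2)
        coef, intercept, _ = fit_sparse_model(X[train], y[train], cfg)
        r2, _ = variance_explained(X[test] @ coef + intercept, y[test])
        assert abs(r2) < 0.3

    def test_too_few_rows_for_cv_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="cv_folds"):
            fit_sparse_model(X, np.arange(5.0), FitConfig(cv_folds=10))


class TestVarianceExplained:
    def test_perfect_and_mean_only_predictions(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert variance_explained(y, y)[0] == pytest.approx(1.0)
        assert variance_explained(np.full(4, y.mean()), y)[0] == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(3), np.ones(3))

    def test_oracle_model_hits_the_noise_floor(self):
        """Predicting with the true coefficients leaves only measurement
        noise: R^2 ~ 1 - noise_var / var(y) and ~1.0 after rescaling by
        the maximum explainable fraction."""
        sim = simulate_landscape(SimulationConfig(seed=19))
        land = sim.landscape
        clean = simulate_landscape(SimulationConfig(seed=19, noise_sd=0))
        pred = clean.landscape.phenotype_vector()
        y = land.phenotype_vector()
        r2, r2_of_max = variance_explained(pred, y, technical_variance=4.0)
        assert r2 == pytest.approx(1 - 4.0 / y.var(), abs=0.02)
        assert r2_of_max == pytest.approx(1.0, abs=0.03)


class TestRepeatedFits:
    def test_single_model_summary_degenerates_to_the_fit(self, small_noisy_landscape):
        cfg = FitConfig(
            max_order=2, n_models=1, cv_repeats=1, train_fraction=0.8, seed=5
        )
        summary = repeated_fits(small_noisy_landscape.landscape, cfg)
        t = summary.table
        assert (t["q25"] == t["median"]).all()
        assert (t["q75"] == t["median"]).all()
        assert (t["nonzero"] == (t["median"] != 0)).all()

    def test_recovers_interacting_pair_support(self, small_noisy_landscape):
        cfg = FitConfig(max_order=2, n_models=5, cv_repeats=1, train_fraction=0.8, seed=6)
        summary = repeated_fits(small_noisy_landscape.landscape, cfg)
        t = summary.table
        nz2 = t[(t["order"] == 2) & t["nonzero"]]
        pairs = {
            tuple(k + 1 for k, a in enumerate(map(int, s.split(","))) if a)
            for s in nz2["states"]
        }
        assert (1, 3) in pairs

    def test_training_set_below_fold_count_rejected(self, small_noisy_landscape):
        cfg = FitConfig(train_fraction=0.04, cv_folds=10, n_models=1)
        with pytest.raises(ValueError, match="cv_folds"):
            repeated_fits(small_noisy_landscape.landscape, cfg)


@pytest.fixture(scope="module")
def default_simulation():
    return simulate_landscape(SimulationConfig(seed=0))


class TestModelComplexityTrends:
    """Directional properties of sparse-model complexity on the
    standard simulation, measured by the summary's non-zero set (the
    coefficients whose IQR across repeated fits excludes zero)."""

    @staticmethod
    def nonzero_count(summary):
        return int(summary.table["nonzero"].sum())

    def test_one_hot_models_retain_at_least_as_many_coefficients(
        self, default_simulation
    ):
        land = default_simulation.landscape
        counts = {}
        for enc in ("background_averaged", "one_hot"):
            cfg = FitConfig(
                encoding=enc, train_fraction=0.64, n_models=4, cv_repeats=1, seed=0
            )
            counts[enc] = self.nonzero_count(repeated_fits(land, cfg))
        assert counts["one_hot"] >= counts["background_averaged"]

    def test_less_training_data_never_increases_model_complexity(
        self, default_simulation
    ):
        land = default_simulation.landscape
        counts = []
        for frac in (0.64, 0.16, 0.04):
            cfg = FitConfig(train_fraction=frac, n_models=4, cv_repeats=1, seed=0)
            counts.append(self.nonzero_count(repeated_fits(land, cfg)))
        assert counts[0] >= counts[1] >= counts[2]
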