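"""Tests for preprocessing (near-zero variance, decorrelation, VIF), the
elastic-net solver, inner CV model selection, the outer protocol, and the
feature-importance score."""

import numpy as np
import pandas as pd
import pytest

from _oracles import lasso_coordinate_descent, vif_by_ols
from sleepvar.prediction import (ElasticNetConfig, assemble_features,
                                 compute_vif, elastic_net_fit,
                                 feature_importance, flag_near_zero_variance,
                                 inner_select_alpha, lambda_path,
                                 outer_protocol, preprocess_features,
                                 remove_correlated, _standardize)


def planted_matrix(seed=0, n=96, n_pairs=3, r=0.9, p=17):
    """Gaussian feature matrix with planted correlated pairs."""
    rng = np.random.default_rng(seed)
    base = p - n_pairs
    X = rng.normal(size=(n, base))
    cols = {f"f{j}": X[:, j] for j in range(base)}
    for k in range(n_pairs):
        partner = r * X[:, k] + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        cols[f"f{k}_twin"] = partner
    return pd.DataFrame(cols)


class TestNearZeroVariance:
    def test_constant_flagged(self):
        assert flag_near_zero_variance([3.0] * 96)

    def test_continuous_not_flagged(self, rng):
        assert not flag_near_zero_variance(rng.normal(size=96))

    def test_ratio_exactly_19_not_flagged(self):
        col = [0] * 95 + [1] * 5
        assert not flag_near_zero_variance(col)      # 95/5 = 19, rule needs > 19

    def test_dominant_mode_flagged(self):
        col = [0] * 98 + [1, 2]
        assert flag_near_zero_variance(col)          # 3/100 unique, ratio 98 > 19

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flag_near_zero_variance([])


class TestRemoveCorrelated:
    def test_identical_columns(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        kept = remove_correlated(df)
        assert len(kept) == 2 and "c" in kept

    def test_independent_untouched(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
        assert remove_correlated(df) == list("abcdef")

    def test_planted_pairs_postcondition(self):
        df = planted_matrix(seed=5)
        kept = remove_correlated(df, threshold=0.7)
        corr = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.7
        assert len(kept) <= len(df.columns) - 3     # at least one per planted pair


class TestVIF:
    def test_orthogonal_columns(self):
        n = 40
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        assert compute_vif(X).to_numpy() == pytest.approx([1.0, 1.0])

    def test_near_dependence_explodes(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        df = pd.DataFrame({"a": a, "b": b, "c": a + b + rng.normal(0, 1e-3, 50)})
        assert compute_vif(df)["c"] > 1e3

    def test_matches_ols_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(120, 5)) @ rng.normal(size=(5, 5)))
        df.columns = [f"x{j}" for j in range(5)]
        assert compute_vif(df).to_numpy() == pytest.approx(vif_by_ols(df.to_numpy()))

    def test_rank_deficient_named(self, rng):
        a = rng.normal(size=30)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear"):
            compute_vif(df)


class TestElasticNetFit:
    def _problem(self, seed=3, n=20, p=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.array([2.0, -1.0, 0.0, 0.5, 0.0])
        y = X @ beta + rng.normal(0, 0.3, n)
        return X, y

    def test_bad_args(self):
        X, y = self._problem()
        with pytest.raises(ValueError):
            elastic_net_fit(X, y, alpha=0.5, lam=-1)
        with pytest.raises(ValueError):
            elastic_net_fit(X, y, alpha=1.5, lam=0.1)

    def test_large_lambda_all_zero(self):
        X, y = self._problem()
        fit = elastic_net_fit(X, y, alpha=1.0, lam=1e6)
        assert np.all(fit.coef == 0)

    def test_lambda_zero_equals_ols(self):
        X, y = self._problem()
        fit = elastic_net_fit(X, y, alpha=0.5, lam=0.0)
        Xs, _, _ = _standardize(X)
        ols = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)[0]
        assert fit.coef == pytest.approx(ols, abs=1e-6)

    def test_lasso_matches_coordinate_descent_oracle(self):
        X, y = self._problem()
        Xs, _, _ = _standardize(X)
        yc = y - y.mean()
        for lam in (0.01, 0.1, 0.5):
            fit = elastic_net_fit(X, y, alpha=1.0, lam=lam)
            oracle = lasso_coordinate_descent(Xs, yc, lam)
            assert fit.coef == pytest.approx(oracle, abs=1e-5)

    def test_objective_no_worse_than_zero_and_ols(self):
        X, y = self._problem(seed=9)
        Xs, _, _ = _standardize(X)
        yc = y - y.mean()
        n = len(y)

        def objective(b, alpha, lam):
            fit_term = np.sum((yc - Xs @ b) ** 2) / (2 * n)
            pen = lam * np.sum((1 - alpha) / 2 * b ** 2 + alpha * np.abs(b))
            return fit_term + pen

        for alpha in (0.0, 0.3, 1.0):
            for lam in (0.01, 0.2):
                fit = elastic_net_fit(X, y, alpha, lam)
                obj = objective(fit.coef, alpha, lam)
                assert obj <= objective(np.zeros(X.shape[1]), alpha, lam) + 1e-12
                ols = np.linalg.lstsq(Xs, yc, rcond=None)[0]
                assert obj <= objective(ols, alpha, lam) + 1e-12

    def test_l1_norm_shrinks_with_lambda(self):
        X, y = self._problem(seed=11)
        for alpha in (0.3, 1.0):
            norms = [np.abs(elastic_net_fit(X, y, alpha, lam).coef).sum()
                     for lam in np.logspace(-3, 1, 12)]
            assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_lambda_max_zeroes_path_start(self):
        X, y = self._problem(seed=13)
        Xs, _, _ = _standardize(X)
        yc = y - y.mean()
        lams = lambda_path(Xs, yc, alpha=1.0, n_lambda=10)
        fit = elastic_net_fit(X, y, alpha=1.0, lam=lams[0])
        assert np.all(np.abs(fit.coef) < 1e-10)


class TestInnerSelection:
    def test_single_alpha_grid(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] + rng.normal(0, 0.5, 60)
        cfg = ElasticNetConfig(alpha_grid=(0.35,), n_inner_reps=2, n_lambda=20)
        sel = inner_select_alpha(X, y, cfg, rng)
        assert sel.alpha == 0.35

    def test_too_few_rows(self, rng):
        cfg = ElasticNetConfig(n_inner_reps=1)
        with pytest.raises(ValueError):
            inner_select_alpha(rng.normal(size=(10, 3)), rng.normal(size=10), cfg)

    def test_sparse_signal_selected(self):
        """2 true predictors of 10 at high SNR: the chosen model keeps them."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            y = 3 * X[:, 2] - 2 * X[:, 7] + rng.normal(0, 0.3, 100)
            cfg = ElasticNetConfig(n_inner_reps=3, n_lambda=30, seed=seed)
            sel = inner_select_alpha(X, y, cfg, np.random.default_rng(seed))
            fit = elastic_net_fit(X, y, sel.alpha, sel.lam)
            if fit.selected[2] and fit.selected[7]:
                hits += 1
        assert hits >= 9


class TestImportance:
    def test_arithmetic(self):
        sel = np.array([[1, 0], [1, 0], [1, 1]])
        r2 = np.array([0.5, 0.5, 0.5])
        fsig = np.array([1, 1, 0])
        imp = feature_importance(sel, r2, fsig, ["a", "b"], denominator=2)
        assert imp.loc[imp.feature == "a", "raw"].iloc[0] == pytest.approx(0.5)
        assert imp.loc[imp.feature == "b", "raw"].iloc[0] == pytest.approx(0.0)
        assert imp["normalized"].max() == 1.0

    def test_always_selected_full_weight(self):
        sel = np.ones((100, 1), dtype=int)
        imp = feature_importance(sel, np.full(100, 0.5), np.ones(100), ["a"])
        assert imp["raw"].iloc[0] == pytest.approx(0.5)

    def test_all_zero_stays_zero(self):
        imp = feature_importance(np.zeros((10, 3), dtype=int), np.zeros(10),
                                 np.zeros(10), list("abc"))
        assert (imp["normalized"] == 0).all()

    def test_bounds(self, rng):
        S, p = 30, 6
        sel = rng.integers(0, 2, size=(S, p))
        r2 = rng.uniform(0, 0.9, S)
        fsig = rng.integers(0, 2, S)
        imp = feature_importance(sel, r2, fsig, [f"f{j}" for j in range(p)])
        assert (imp["raw"] >= 0).all()
        assert (imp["raw"] <= r2.max() + 1e-12).all()
        assert imp["normalized"].between(0, 1).all()


class TestOuterProtocol:
    def _table(self, seed=0, n_participants=40):
        rng = np.random.default_rng(seed)
        pid = np.repeat([f"P{i}" for i in range(n_participants)], 2)
        n = len(pid)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = 2 * X["a"].to_numpy() + rng.normal(0, 0.4, n)
        return X, y, pid

    def _cfg(self, **kw):
        defaults = dict(n_outer_reps=2, n_inner_reps=2, n_lambda=15, seed=7)
        defaults.update(kw)
        return ElasticNetConfig(**defaults)

    def test_single_outer_rep(self):
        X, y, pid = self._table()
        res = outer_protocol(X, y, pid, self._cfg(n_outer_reps=1))
        assert len(res.records) == 1
        assert res.selections.shape == (1, 5)

    def test_participant_level_split(self):
        X, y, pid = self._table()
        res = outer_protocol(X, y, pid, self._cfg())
        # 70/30 of 40 participants, 2 rows each
        assert (res.records["n_train"] == 56).all()
        assert (res.records["n_test"] == 24).all()

    def test_reproducibility(self):
        X, y, pid = self._table()
        a = outer_protocol(X, y, pid, self._cfg())
        b = outer_protocol(X, y, pid, self._cfg())
        pd.testing.assert_frame_equal(a.records, b.records)
        assert np.array_equal(a.selections, b.selections)

    def test_strong_signal_feature_wins(self):
        X, y, pid = self._table(seed=2)
        res = outer_protocol(X, y, pid, self._cfg(n_outer_reps=4))
        top = res.importance.sort_values("normalized", ascending=False).iloc[0]
        assert top["feature"] == "a"
        assert top["normalized"] == 1.0


class TestAssembly:
    def test_seventeen_columns(self, small_cohort):
        from sleepvar import iiv, scoring
        nights = scoring.nights_to_frame(
            [scoring.score_night(s) for s in small_cohort.epochs])
        windows = iiv.build_window_summaries(nights, small_cohort.visits,
                                             small_cohort.profiles)
        X, y, groups = assemble_features(windows, small_cohort.scales,
                                         small_cohort.profiles)
        assert X.shape[1] == 17
        assert len(y) == len(groups) == len(X)
        assert not X.isna().any().any()
        assert set(X["sex"].unique()) <= {0, 1}
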