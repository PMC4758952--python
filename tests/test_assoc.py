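"""Correlation matrix, partial correlations, best-subset and LASSO."""

import numpy as np
import pandas as pd
import pytest

from ctdbalance.assoc import (
    CTDMarkModel,
    best_subset,
    build_mark_table,
    lasso_1se,
    lasso_coef_at_zero,
    partial_correlation,
    spearman_matrix,
    standardize,
)


def exact_corr_data(C: np.ndarray, n: int = 60, seed: int = 0) -> pd.DataFrame:
    """Data whose *sample* correlation matrix equals C exactly.

    Random Gaussian columns are orthonormalized (so their sample correlation
    is the identity) and then mixed with the Cholesky factor of C.
    """
    rng = np.random.default_rng(seed)
    p = C.shape[0]
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Z = Q / Q.std(axis=0, ddof=1)
    L = np.linalg.cholesky(C)
    return pd.DataFrame(Z @ L.T, columns=[f"v{i}" for i in range(p)])


def planted_regression(n=1500, seed=0):
    """y = 0.6*S7p + 0.5*K7ac - 0.3*K7me1 + noise, R^2 around 0.6."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n, 5)), columns=["S7p", "K7ac", "K7me1", "mock", "CpG"]
    )
    signal = 0.6 * df["S7p"] + 0.5 * df["K7ac"] - 0.3 * df["K7me1"]
    df["S2p"] = signal + rng.normal(scale=signal.std() * np.sqrt(2 / 3), size=n)
    return standardize(df)


class TestSpearmanMatrix:
    def test_hand_computed_coefficient(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4], "mRNA": [1, 2, 3, 4]})
        m = spearman_matrix(t)
        assert m.loc["x", "y"] == pytest.approx(0.8)

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        m = spearman_matrix(t, order_by=None)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_reversal_negates(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 5]})
        m1 = spearman_matrix(t, order_by=None)
        t["y"] = -t["y"]
        m2 = spearman_matrix(t, order_by=None)
        assert m1.loc["x", "y"] == pytest.approx(-m2.loc["x", "y"])

    def test_ordering_by_mrna(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        t = pd.DataFrame(
            {
                "strong": base + 0.1 * rng.normal(size=100),
                "weak": 0.3 * base + rng.normal(size=100),
                "mRNA": base + 0.5 * rng.normal(size=100),
            }
        )
        m = spearman_matrix(t)
        assert list(m.columns)[-1] == "mRNA"
        corrs = m["mRNA"].to_numpy()
        assert (np.diff(corrs) >= 0).all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.lognormal(size=(50, 3)), columns=list("abc"))
        m1 = spearman_matrix(t, order_by=None)
        m2 = spearman_matrix(np.log(t) * 2 + 5, order_by=None)
        assert np.allclose(m1, m2)


class TestPartialCorrelation:
    def test_empty_conditioning_equals_marginal(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(40, 2)), columns=["x", "y"])
        r, _ = partial_correlation(t, "x", "y", [], method="pearson")
        assert r == pytest.approx(np.corrcoef(t["x"], t["y"])[0, 1], abs=1e-12)

    def test_recursive_formula_single_conditioner(self):
        C = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.72], [0.8, 0.72, 1.0]])
        t = exact_corr_data(C)
        r, _ = partial_correlation(t, "v0", "v1", ["v2"], method="pearson")
        expected = (0.9 - 0.8 * 0.72) / np.sqrt((1 - 0.64) * (1 - 0.72**2))
        assert r == pytest.approx(expected, abs=1e-10)
        assert r == pytest.approx(0.7782, abs=1e-3)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_residual_regression_oracle(self, method):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("xyabc"))
        t["y"] += 0.5 * t["a"] - 0.4 * t["x"]
        data = t.rank() if method == "spearman" else t
        given = ["a", "b", "c"]
        Z = np.column_stack([np.ones(len(data)), data[given]])
        rx = data["x"] - Z @ np.linalg.lstsq(Z, data["x"], rcond=None)[0]
        ry = data["y"] - Z @ np.linalg.lstsq(Z, data["y"], rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        r, _ = partial_correlation(t, "x", "y", given, method=method)
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.normal(size=(120, 4)), columns=list("xyzw"))
        r, p = partial_correlation(t, "x", "y", ["z", "w"], method="pearson")
        ref = pingouin.partial_corr(t, x="x", y="y", covar=["z", "w"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_singular_conditioning_raises(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "y", "z"])
        t["z2"] = t["z"]
        with pytest.raises(ValueError, match="collinear|singular"):
            partial_correlation(t, "x", "y", ["z", "z2"])

    def test_insufficient_observations(self):
        t = pd.DataFrame(np.eye(4), columns=list("wxyz"))
        with pytest.raises(ValueError):
            partial_correlation(t, "w", "x", ["y", "z"])


class TestBestSubset:
    def test_duplicated_response_gives_perfect_fit(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "S2p"])
        t["dup"] = t["S2p"]
        models = best_subset(t, "S2p", ["a", "b", "dup"], max_size=2)
        assert models[1][0].predictors == ("dup",)
        assert models[1][0].adj_r2 == pytest.approx(1.0)

    def test_planted_model_selection(self):
        t = planted_regression(seed=13)
        models = best_subset(t, "S2p", ["S7p", "K7ac", "K7me1", "mock", "CpG"], max_size=3)
        assert set(models[2][0].predictors) == {"S7p", "K7ac"}
        m3 = models[3][0]
        assert set(m3.predictors) == {"S7p", "K7ac", "K7me1"}
        assert m3.coefficients["K7me1"] < 0
        assert m3.significance["K7me1"] == "***"

    def test_adjusted_r2_formula(self):
        # adj R^2 = 1 - (1 - R^2)(n-1)/(n-p-1)
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "y"])
        t["y"] = t["a"] + t["b"] + rng.normal(size=100)
        m = best_subset(t, "y", ["a", "b"], max_size=2)[2][0]
        import statsmodels.api as sm

        fit = sm.OLS(t["y"], sm.add_constant(t[["a", "b"]])).fit()
        expected = 1 - (1 - fit.rsquared) * 99 / 97
        assert m.adj_r2 == pytest.approx(expected, abs=1e-12)

    def test_full_model_cp_is_p_plus_one(self):
        t = planted_regression(n=300, seed=2)
        preds = ["S7p", "K7ac", "K7me1", "mock", "CpG"]
        models = best_subset(t, "S2p", preds, max_size=5)
        full = [m for m in models[5] if set(m.predictors) == set(preds)][0]
        assert full.cp == pytest.approx(len(preds) + 1)

    def test_too_few_observations(self):
        t = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                         columns=["a", "b", "c", "y"])
        with pytest.raises(ValueError):
            best_subset(t, "y", ["a", "b", "c"])


class TestLasso:
    def test_pure_noise_shrinks_to_zero(self):
        rng = np.random.default_rng(21)
        t = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=["a", "b", "c", "d", "e", "y"])
        res = lasso_1se(t, "y", ["a", "b", "c", "d", "e"], seed=3)
        assert (res.coefficients == 0).all()

    def test_planted_model_drops_mock_and_keeps_negative_methylation(self):
        t = planted_regression(seed=17)
        res = lasso_1se(t, "S2p", ["S7p", "K7ac", "K7me1", "mock", "CpG"], seed=17)
        assert res.coefficients["mock"] == 0
        assert res.coefficients["K7me1"] < 0
        assert res.coefficients["S7p"] > 0 and res.coefficients["K7ac"] > 0

    def test_path_endpoint_matches_ols(self):
        t = planted_regression(n=40, seed=9)
        preds = ["S7p", "K7ac", "K7me1"]
        from sklearn.linear_model import Lasso

        ols = lasso_coef_at_zero(t, "S2p", preds)
        near_zero = Lasso(alpha=1e-9, max_iter=200_000).fit(t[preds], t["S2p"])
        assert np.allclose(near_zero.coef_, ols.to_numpy(), atol=1e-6)

    def test_seeded_folds_are_reproducible(self):
        t = planted_regression(n=300, seed=1)
        r1 = lasso_1se(t, "S2p", seed=5)
        r2 = lasso_1se(t, "S2p", seed=5)
        assert np.allclose(r1.cv_mean, r2.cv_mean)
        assert r1.alpha_selected == r2.alpha_selected


class TestModelInterface:
    def test_fit_returns_complete_results(self):
        rng = np.random.default_rng(6)
        cols = ["K7me1", "K7me2", "K7ac", "8WG16", "S5p", "S7p", "mock", "CpG"]
        t = pd.DataFrame(rng.normal(size=(150, 8)), columns=cols)
        t["S2p"] = 0.5 * t["S7p"] + 0.4 * t["K7ac"] + rng.normal(size=150)
        t["mRNA"] = t["S2p"] + rng.normal(size=150)
        t = standardize(t)
        res = CTDMarkModel(t, response="S2p").fit(seed=0)
        assert res.spearman.shape == (10, 10)
        assert not res.partial_correlations.empty
        assert set(res.subset_models) == {1, 2, 3, 4, 5}
        summary = res.summary()
        assert "LASSO" in summary and "Best subsets" in summary

    def test_build_mark_table_standardizes(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.lognormal(size=(50, 3)), columns=["K7me2", "K7ac", "S2p"],
            index=[f"g{i}" for i in range(50)],
        )
        t = build_mark_table(counts)
        assert np.allclose(t.mean(), 0, atol=1e-10)
        assert np.allclose(t.std(ddof=1), 1, atol=1e-10)

    def test_unknown_response_raises(self):
        t = pd.DataFrame({"a": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            CTDMarkModel(t, response="S2p")
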