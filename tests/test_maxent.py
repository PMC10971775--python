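"""The maximum-entropy core: feature expansion, the penalized fit and its
KKT moment condition, prediction scales, and serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from urbanshift.maxent import (
    FeatureSpec,
    MaxEnt,
    MaxEntResults,
    expand_features,
    fit_lq_optimum,
)


@pytest.fixture(scope="module")
def one_var_data():
    rng = np.random.default_rng(0)
    bg = pd.DataFrame({"v": rng.uniform(0.0, 10.0, 200)})
    pres = pd.DataFrame({"v": rng.normal(6.0, 1.0, 100).clip(0.0, 10.0)})
    return pres, bg


class TestExpandFeatures:
    RANGES = {"v": (0.0, 10.0)}

    def test_linear_midpoint_and_quadratic(self):
        X, names, _ = expand_features(
            pd.DataFrame({"v": [5.0]}), FeatureSpec("LQ"), self.RANGES
        )
        assert names == ["L(v)", "Q(v)"]
        np.testing.assert_allclose(X[0], [0.5, 0.25])

    def test_forward_hinge_closed_form(self):
        # 4 knots put a knot at 0.4; u=0.7 -> (0.7-0.4)/(1-0.4) = 0.5
        spec = FeatureSpec("HQ", n_hinge_knots=4)
        X, names, _ = expand_features(pd.DataFrame({"v": [7.0]}), spec, self.RANGES)
        assert X[0][names.index("H+(v,0.400)")] == pytest.approx(0.5)
        # reverse hinge at knot 0.8: (0.8-0.7)/0.8 = 0.125
        assert X[0][names.index("H-(v,0.800)")] == pytest.approx(0.125)

    def test_threshold_indicators_and_clamping(self):
        spec = FeatureSpec("QPHT", n_hinge_knots=4)
        ranges = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        X, names, classes = expand_features(
            pd.DataFrame({"a": [2.0], "b": [0.5]}), spec, ranges
        )
        # a clamps to u=1: every threshold indicator for a fires
        t_a = [x for x, n, c in zip(X[0], names, classes) if c == "T" and "(a," in n]
        assert t_a == [1.0] * 4
        assert X[0][names.index("P(a,b)")] == pytest.approx(0.5)

    def test_grid_of_class_sets_has_expected_widths(self):
        ranges = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        df = pd.DataFrame({"a": [0.3], "b": [0.6]})
        widths = {}
        for cls in ("L", "Q", "P", "LQ", "HQ", "QPH", "QPHT", "LQHP"):
            X, _, _ = expand_features(df, FeatureSpec(cls, n_hinge_knots=5), ranges)
            widths[cls] = X.shape[1]
        assert widths == {"L": 2, "Q": 2, "P": 1, "LQ": 4, "HQ": 22,
                          "QPH": 23, "QPHT": 33, "LQHP": 25}


class TestFit:
    def test_null_data_gives_uniform_distribution(self):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"v": rng.uniform(0, 1, 500)})
        pres = pd.DataFrame({"v": rng.uniform(0, 1, 200)})
        res = MaxEnt(pres, bg, FeatureSpec("LQ", reg_multiplier=3.0)).fit()
        # presences ~ background: the fitted distribution approaches uniform
        # (entropy -> log n_bg) and the logistic output stays near 0.5
        assert res.entropy == pytest.approx(np.log(500), abs=0.02)
        np.testing.assert_allclose(res.predict(bg, scale="logistic"), 0.5, atol=0.1)
        # a literally-zero model is exactly uniform at 0.5
        null = MaxEntResults(
            spec=res.spec, var_names=res.var_names,
            variable_ranges=res.variable_ranges,
            params=np.zeros_like(res.params), feature_names=res.feature_names,
            offset=np.log(500), entropy=np.log(500),
        )
        np.testing.assert_allclose(null.predict(bg, scale="logistic"), 0.5)

    def test_moment_matching_at_zero_regularization(self, one_var_data):
        pres, bg = one_var_data
        model = MaxEnt(pres, bg, FeatureSpec("L", reg_multiplier=0.0))
        res = model.fit()
        q = np.exp(model.X_bg @ res.params - res.offset)
        fitted_mean = q @ model.X_bg
        np.testing.assert_allclose(fitted_mean, model.X_pres.mean(axis=0), atol=1e-4)

    def test_matches_brute_force_grid_search(self, one_var_data):
        """1-variable L-only fit vs exhaustive scan of the single coefficient."""
        pres, bg = one_var_data
        model = MaxEnt(pres, bg, FeatureSpec("L", reg_multiplier=0.0))
        res = model.fit()
        xb = model.X_bg[:, 0]
        xp_mean = model.X_pres[:, 0].mean()

        def objective(c):
            return logsumexp(c * xb) - c * xp_mean

        grid = np.linspace(-50, 50, 100_001)
        best = grid[np.argmin([objective(c) for c in grid[::100]]) * 100]
        fine = np.linspace(best - 1, best + 1, 20_001)
        oracle = fine[np.argmin([objective(c) for c in fine])]
        assert res.params[0] == pytest.approx(oracle, abs=1e-3)

    def test_gaussian_niche_recovered_by_lq(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"v": rng.uniform(0, 10, 1000)})
        truth_opt, breadth = 6.0, 1.2
        pres = pd.DataFrame({"v": rng.normal(truth_opt, breadth, 500).clip(0, 10)})
        est = fit_lq_optimum(pres, bg, "v")
        assert abs(est - truth_opt) < 0.5 * breadth

    def test_sparsity_monotone_in_regularization(self, one_var_data):
        pres, bg = one_var_data
        nz = []
        for r in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
            res = MaxEnt(pres, bg, FeatureSpec("QPHT", r, n_hinge_knots=6)).fit()
            nz.append(res.n_nonzero)
        assert all(a >= b for a, b in zip(nz, nz[1:]))

    def test_raw_distribution_sums_to_one(self, one_var_data):
        pres, bg = one_var_data
        res = MaxEnt(pres, bg, FeatureSpec("HQ", 1.0, n_hinge_knots=6)).fit()
        assert res.predict(bg, scale="raw").sum() == pytest.approx(1.0, abs=1e-8)

    def test_too_few_rows_rejected(self, one_var_data):
        pres, bg = one_var_data
        with pytest.raises(ValueError):
            MaxEnt(pres.iloc[:3], bg)
        with pytest.raises(ValueError):
            MaxEnt(pres, bg.iloc[:10])


class TestPredict:
    def test_hand_set_model_closed_form(self):
        """Two coefficients, offset and H given: logistic by hand."""
        res = MaxEntResults(
            spec=FeatureSpec("L"), var_names=["a", "b"],
            variable_ranges={"a": (0.0, 1.0), "b": (0.0, 1.0)},
            params=np.array([1.0, -2.0]), feature_names=["L(a)", "L(b)"],
            offset=0.5, entropy=2.0, threshold=0.5,
        )
        pts = pd.DataFrame({"a": [0.0, 1.0, 0.5], "b": [0.0, 0.0, 1.0]})
        eta = np.array([0.0, 1.0, 0.5 - 2.0])
        raw = np.exp(eta - 0.5)
        expected = 0.5 * np.exp(2.0) * raw / (1 - 0.5 + 0.5 * np.exp(2.0) * raw)
        np.testing.assert_allclose(res.predict(pts, scale="logistic"), expected)
        np.testing.assert_allclose(res.predict(pts, scale="raw"), raw)

    def test_logistic_preserves_raw_ranking(self, one_var_data):
        pres, bg = one_var_data
        res = MaxEnt(pres, bg, FeatureSpec("LQ", 1.0)).fit()
        raw = res.predict(bg, scale="raw")
        logi = res.predict(bg, scale="logistic")
        assert (np.argsort(raw) == np.argsort(logi)).all()
        assert ((logi >= 0) & (logi <= 1)).all()

    def test_missing_column_raises(self, one_var_data):
        pres, bg = one_var_data
        res = MaxEnt(pres, bg).fit()
        with pytest.raises(KeyError):
            res.predict(pd.DataFrame({"other": [1.0]}))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, one_var_data, tmp_path):
        pres, bg = one_var_data
        res = MaxEnt(pres, bg, FeatureSpec("QPH", 1.0, n_hinge_knots=6)).fit()
        res.threshold = 0.4
        res.metrics["mean_train_AUC"] = 0.8
        path = tmp_path / "model.json"
        res.save(path)
        back = MaxEntResults.load(path)
        np.testing.assert_array_equal(back.params, res.params)
        assert back.threshold == 0.4
        np.testing.assert_allclose(back.predict(bg, scale="logistic"),
                                   res.predict(bg, scale="logistic"))

    def test_summary_mentions_spec(self, one_var_data):
        pres, bg = one_var_data
        res = MaxEnt(pres, bg, FeatureSpec("LQ", 1.5)).fit()
        s = res.summary()
        assert "LQ" in s and "1.5" in s
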