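"""Spatial blocks, AUC, continuous Boyce index, tuning, contributions,
threshold selection, and the quality gate."""

import numpy as np
import pandas as pd
import pytest

from urbanshift.evaluation import (
    FoldError,
    TuningResult,
    assign_blocks,
    auc,
    boyce,
    default_grid,
    percent_contribution,
    quality_gate,
    random_folds,
    select_threshold,
    tune,
)
from urbanshift.maxent import FeatureSpec, MaxEnt


def _brute_auc(p, b):
    wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
    return wins / (len(p) * len(b))


class TestAssignBlocks:
    def test_one_presence_per_quadrant(self):
        pres = pd.DataFrame({"x": [0.0, 10.0, 0.0, 10.0], "y": [0.0, 0.0, 10.0, 10.0]})
        bg = pd.DataFrame({"x": [1.0], "y": [1.0]})
        f = assign_blocks(pres, bg)
        assert sorted(f.presence_folds) == [1, 2, 3, 4]
        assert f.background_folds[0] == 1  # SW of the medians

    def test_unbalanced_background_is_legal(self):
        rng = np.random.default_rng(0)
        pres = pd.DataFrame({"x": rng.uniform(0, 10, 40), "y": rng.uniform(0, 10, 40)})
        bg = pd.DataFrame({"x": np.full(30, 0.1), "y": np.full(30, 0.1)})
        f = assign_blocks(pres, bg)
        assert (f.background_folds == 1).all()

    def test_counts_match_brute_force_median_split(self):
        rng = np.random.default_rng(1)
        pres = pd.DataFrame({"x": rng.uniform(0, 1, 100), "y": rng.uniform(0, 1, 100)})
        bg = pres.iloc[:10]
        f = assign_blocks(pres, bg)
        mx, my = pres["x"].median(), pres["y"].median()
        brute = (
            1 + (pres["x"] > mx).astype(int) + 2 * (pres["y"] > my).astype(int)
        ).to_numpy()
        np.testing.assert_array_equal(f.presence_folds, brute)

    def test_empty_quadrant_raises_fold_error(self):
        pres = pd.DataFrame({"x": [0, 0, 1, 1.0], "y": [0, 0, 1, 1.0]})
        with pytest.raises(FoldError):
            assign_blocks(pres, pres)


class TestAUC:
    def test_separation_and_ties(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_spec_toy_example(self):
        # pairs won 5 of 6 -> 5/6
        assert auc([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_equals_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n_p = rng.integers(1, 50)
            n_b = rng.integers(1, 50)
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n_p)
            b = rng.uniform(0, 1, n_b).round(1)
            assert auc(p, b) == pytest.approx(_brute_auc(p, b))


class TestBoyce:
    def test_perfect_ranking_approaches_one(self):
        rng = np.random.default_rng(3)
        bg = rng.uniform(0, 1, 4000)
        pres = rng.beta(5, 1, 2000)  # density increasing with suitability
        assert boyce(pres, bg) > 0.95

    def test_hand_computed_three_window_toy(self):
        # windows [-.25,.25],[.25,.75],[.75,1.25]; P/E = .75,.75,1.5
        # Spearman(ranks [1.5,1.5,3] vs [1,2,3]) = sqrt(3)/2
        pres = [0.1, 0.6, 0.9, 0.95]
        bg = [0.1, 0.2, 0.5, 0.6, 0.9, 0.95]
        got = boyce(pres, bg, n_windows=3, window_width=0.5)
        assert got == pytest.approx(np.sqrt(3) / 2)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(0, 1, 1000)
        pres = rng.beta(3, 1, 500)
        direct = boyce(pres, bg)
        squashed = boyce(pres**2, bg**2)  # strictly increasing transform
        # both stay strongly positive and inside [-1, 1]
        for v in (direct, squashed):
            assert -1.0 <= v <= 1.0 and v > 0.5

    def test_too_few_windows_is_nan(self):
        assert np.isnan(boyce([0.5], [0.5], n_windows=3, window_width=0.01))


class TestSelectThreshold:
    def test_perfect_separation_takes_smallest_presence_score(self):
        t = select_threshold([0.8, 0.85, 0.9], [0.1, 0.2])
        assert t == 0.8

    def test_spec_toy_by_exhaustive_scan(self):
        # max(sens+spec) = 1 + 2/3 at threshold 0.8
        assert select_threshold([0.8, 0.9], [0.1, 0.2, 0.85]) == pytest.approx(0.8)

    def test_raising_threshold_shrinks_presence_calls(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 200)
        t = select_threshold(scores[:100], scores[100:])
        n_at = (scores >= t).sum()
        n_above = (scores >= t + 0.1).sum()
        assert n_above <= n_at

    def test_equal_sens_spec_rule(self):
        t = select_threshold([0.6, 0.7, 0.8], [0.2, 0.3, 0.4], rule="equal_sens_spec")
        assert 0.4 <= t <= 0.6


@pytest.fixture(scope="module")
def niche_data():
    rng = np.random.default_rng(6)
    n_bg = 600
    bg_xy = pd.DataFrame({"x": rng.uniform(0, 100, n_bg),
                          "y": rng.uniform(0, 100, n_bg)})
    bg = pd.DataFrame({"v": rng.uniform(0, 10, n_bg)})
    n_p = 80
    p_xy = pd.DataFrame({"x": rng.uniform(0, 100, n_p),
                         "y": rng.uniform(0, 100, n_p)})
    pres = pd.DataFrame({"v": rng.normal(6.0, 1.0, n_p).clip(0, 10)})
    return pres, bg, p_xy, bg_xy


@pytest.fixture(scope="module")
def two_var_fit():
    rng = np.random.default_rng(7)
    bg = pd.DataFrame({"a": rng.uniform(0, 1, 500), "b": rng.uniform(0, 1, 500)})
    pres = pd.DataFrame({"a": rng.normal(0.7, 0.1, 150).clip(0, 1),
                         "b": rng.uniform(0, 1, 150)})
    res = MaxEnt(pres, bg, FeatureSpec("LQ", 1.0)).fit()
    return res, pres, bg


class TestTune:
    def test_grid_enumerates_48_candidates(self):
        assert len(default_grid()) == 48

    def test_single_candidate_grid_wins(self, niche_data):
        pres, bg, p_xy, bg_xy = niche_data
        grid = [FeatureSpec("LQ", 1.0, n_hinge_knots=6)]
        out = tune(pres, bg, p_xy, bg_xy, grid=grid, seed=0)
        assert out.has_best_model
        assert out.winner_spec.classes == "LQ"
        assert out.winner.threshold is not None
        assert len(out.candidates) == 1

    def test_full_grid_metrics_and_reproducibility(self, niche_data):
        pres, bg, p_xy, bg_xy = niche_data
        grid = default_grid(n_hinge_knots=6)
        out1 = tune(pres, bg, p_xy, bg_xy, grid=grid, seed=0)
        out2 = tune(pres, bg, p_xy, bg_xy, grid=list(reversed(grid)), seed=0)
        assert len(out1.candidates) == 48
        # winner invariant to candidate evaluation order
        assert out1.winner_spec == out2.winner_spec
        m = out1.winner.metrics
        assert m["mean_BCI"] == max(out1.candidates["mean_BCI"].dropna())
        assert -1 <= m["mean_BCI"] <= 1 and 0 <= m["mean_train_AUC"] <= 1

    def test_lq_niche_prefers_quadratic_classes(self):
        # data simulated from a Gaussian (quadratic log-density) niche:
        # the winning class set should usually include Q
        wins = 0
        reps = 6
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            bg = pd.DataFrame({"v": rng.uniform(0, 10, 400)})
            bg_xy = pd.DataFrame({"x": rng.uniform(0, 100, 400),
                                  "y": rng.uniform(0, 100, 400)})
            pres = pd.DataFrame({"v": rng.normal(5.0, 0.8, 60).clip(0, 10)})
            p_xy = pd.DataFrame({"x": rng.uniform(0, 100, 60),
                                 "y": rng.uniform(0, 100, 60)})
            grid = [FeatureSpec(c, r, n_hinge_knots=6)
                    for c in ("L", "Q", "LQ", "HQ") for r in (1.0, 2.0)]
            out = tune(pres, bg, p_xy, bg_xy, grid=grid, seed=rep)
            if out.has_best_model and "Q" in out.winner_spec.classes:
                wins += 1
        assert wins / reps >= 0.7

    def test_random_fold_fallback(self, niche_data):
        pres, bg, p_xy, bg_xy = niche_data
        clustered = p_xy.copy()
        clustered["x"] = 1.0  # all presences on one vertical line
        clustered["y"] = 1.0
        grid = [FeatureSpec("L", 1.0)]
        with pytest.warns(UserWarning, match="random folds"):
            out = tune(pres, bg, clustered, bg_xy, grid=grid, seed=1)
        assert out.folds.method == "random"


class TestPercentContribution:
    def test_active_variable_dominates(self, two_var_fit):
        res, pres, bg = two_var_fit
        pc = percent_contribution(res, pres, bg, seed=0)
        assert pc["a"] > 90.0 and pc["b"] < 10.0
        assert sum(pc.values()) == pytest.approx(100.0, abs=0.1)

    def test_symmetric_variables_split_evenly(self):
        rng = np.random.default_rng(8)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 500), "b": rng.uniform(0, 1, 500)})
        pres = pd.DataFrame({"a": rng.normal(0.7, 0.15, 200).clip(0, 1),
                             "b": rng.normal(0.7, 0.15, 200).clip(0, 1)})
        res = MaxEnt(pres, bg, FeatureSpec("L", 1.0)).fit()
        pc = percent_contribution(res, pres, bg, seed=1)
        assert abs(pc["a"] - 50.0) < 10.0

    def test_all_zero_drops_yield_uniform_shares(self, two_var_fit):
        res, pres, bg = two_var_fit
        null = res.__class__(
            spec=res.spec, var_names=res.var_names,
            variable_ranges=res.variable_ranges,
            params=np.zeros_like(res.params), feature_names=res.feature_names,
            offset=res.offset, entropy=res.entropy,
        )
        pc = percent_contribution(null, pres, bg, seed=2)
        assert pc == {"a": 50.0, "b": 50.0}


class TestQualityGate:
    def _tuning_with_auc(self, train_auc):
        res = type("R", (), {})()
        res.metrics = {"mean_train_AUC": train_auc}
        return TuningResult(candidates=pd.DataFrame(), winner_spec=FeatureSpec(),
                            winner=res)

    def test_auc_boundary_exactly_070_keeps(self):
        keep, reason = quality_gate(self._tuning_with_auc(0.70), n_records=20)
        assert keep and reason == "keep"

    def test_auc_069_drops(self):
        keep, reason = quality_gate(self._tuning_with_auc(0.69), n_records=20)
        assert not keep and "AUC" in reason

    def test_insufficient_records_drop(self):
        keep, reason = quality_gate(self._tuning_with_auc(0.9), n_records=9)
        assert not keep and "insufficient" in reason

    def test_no_best_model_drop(self):
        empty = TuningResult(candidates=pd.DataFrame(), winner_spec=None, winner=None)
        keep, reason = quality_gate(empty, n_records=20)
        assert not keep and reason == "no best model"
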