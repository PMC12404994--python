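"""ROC machinery, correlation pruning, stability selection and panel
evaluation."""

import numpy as np
import pandas as pd
import pytest

import ndproteo as nd


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases = s[y == 1]
    controls = s[y == 0]
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(cases) * len(controls))


class TestRocMetrics:
    def test_perfect_separation(self):
        m = nd.roc_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["auc"] == 1.0
        assert m["youden_j"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_all_tied_scores(self):
        m = nd.roc_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert m["auc"] == 0.5

    def test_pairwise_counting_example(self):
        m = nd.roc_metrics([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert m["auc"] == 0.75      # 3 wins, 1 loss of 4 pairs

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 200))
            scores = rng.choice(np.round(rng.normal(size=50), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            m = nd.roc_metrics(scores, labels)
            assert m["auc"] == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_youden_tie_takes_lower_cutoff(self):
        # cutoffs 0.2 and 0.4 both give J = 0.5; lower one must win
        m = nd.roc_metrics([0.1, 0.2, 0.4, 0.5], [0, 1, 0, 1])
        assert m["cutoff"] == pytest.approx(0.2)

    def test_one_class_rejected(self):
        with pytest.raises(nd.DataError):
            nd.roc_metrics([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_ci_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        small = nd.delong_ci(np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)],
                             np.r_[np.ones(30), np.zeros(30)])
        large = nd.delong_ci(np.r_[rng.normal(1, 1, 500),
                                   rng.normal(0, 1, 500)],
                             np.r_[np.ones(500), np.zeros(500)])
        for ci in (small, large):
            assert ci["ci_low"] <= ci["auc"] <= ci["ci_high"]
        assert large["se"] < small["se"]

    def test_coverage_of_binormal_truth(self):
        # true AUC for N(1,1) cases vs N(0,1) controls is Phi(1/sqrt(2))
        from scipy.stats import norm
        true_auc = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(2)
        covered = 0
        reps = 200
        for _ in range(reps):
            cases = rng.normal(1, 1, 60)
            controls = rng.normal(0, 1, 60)
            ci = nd.delong_ci(np.r_[cases, controls],
                              np.r_[np.ones(60), np.zeros(60)])
            covered += ci["ci_low"] <= true_auc <= ci["ci_high"]
        assert 0.90 <= covered / reps <= 0.99


class TestPruneCorrelated:
    def test_duplicate_column_keeps_lower_q(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=100)
        vals = pd.DataFrame({"P1": base, "P2": base,
                             "P3": rng.normal(size=100)})
        kept = nd.prune_correlated(vals, ["P1", "P2", "P3"],
                                   {"P1": 0.02, "P2": 0.01, "P3": 0.5})
        assert kept == ["P2", "P3"]

    def test_uncorrelated_candidates_unchanged(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(200, 4)),
                            columns=["P1", "P2", "P3", "P4"])
        kept = nd.prune_correlated(vals, list(vals.columns),
                                   {c: 0.01 for c in vals.columns})
        assert kept == sorted(vals.columns)

    def test_chain_pruning_matches_greedy_rule(self):
        # A~B and B~C correlated above threshold, A~C below: greedy walk in
        # q order (A, B, C) keeps A, drops B, keeps C
        rng = np.random.default_rng(5)
        n = 5000
        x1, x2, x3 = rng.normal(size=(3, n))
        a = x1
        b = (x1 + 0.4 * x2) / np.sqrt(1.16)
        c = (b + 0.4 * x3) / np.sqrt(1.16)
        vals = pd.DataFrame({"A": a, "B": b, "C": c})
        r2 = vals.corr() ** 2
        assert r2.loc["A", "B"] > 0.8 and r2.loc["B", "C"] > 0.8
        assert r2.loc["A", "C"] < 0.8
        kept = nd.prune_correlated(vals, ["A", "B", "C"],
                                   {"A": 0.01, "B": 0.02, "C": 0.03})
        assert kept == ["A", "C"]

    def test_missing_candidate_rejected(self):
        vals = pd.DataFrame({"P1": [1.0, 2.0]})
        with pytest.raises(nd.DataError):
            nd.prune_correlated(vals, ["P1", "ZZ"], {"P1": 0.1, "ZZ": 0.2})


class TestStabilitySelection:
    def test_panel_equals_all_when_k_covers_candidates(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(size=(120, 4)),
                            columns=["P1", "P2", "P3", "P4"])
        y = (vals["P1"] + rng.normal(size=120) > 0).astype(int)
        params = nd.PanelParams(n_stability_iters=3, panel_size=4,
                                cv_folds=5, seed=0)
        _, panel, _ = nd.stability_select(vals, y, list(vals.columns),
                                          params)
        assert sorted(panel) == ["P1", "P2", "P3", "P4"]

    def test_strong_predictor_selected_most_often(self):
        rng = np.random.default_rng(7)
        n = 240
        vals = pd.DataFrame(rng.normal(size=(n, 15)),
                            columns=[f"P{i:02d}" for i in range(15)])
        y = (1.5 * vals["P00"] + rng.normal(size=n) > 0).astype(int)
        params = nd.PanelParams(n_stability_iters=8, panel_size=3,
                                cv_folds=5, seed=1)
        freqs, panel, _ = nd.stability_select(vals, y, list(vals.columns),
                                              params)
        assert "P00" in panel
        assert freqs["P00"] == freqs.max()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(size=(100, 8)),
                            columns=[f"P{i}" for i in range(8)])
        y = (vals["P0"] + rng.normal(size=100) > 0).astype(int)
        params = nd.PanelParams(n_stability_iters=3, panel_size=2,
                                cv_folds=5, seed=9)
        a = nd.stability_select(vals, y, list(vals.columns), params)
        b = nd.stability_select(vals, y, list(vals.columns), params)
        pd.testing.assert_series_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_small_class_rejected(self):
        vals = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)),
                            columns=["P1", "P2", "P3"])
        y = np.r_[np.ones(3), np.zeros(17)].astype(int)
        with pytest.raises(nd.DataError, match="folds"):
            nd.stability_select(vals, y, list(vals.columns),
                                nd.PanelParams(n_stability_iters=1,
                                               panel_size=2))


class TestEvaluatePanel:
    def build(self, n=200, seed=10, effect=3.0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        vals = pd.DataFrame({
            "P1": rng.normal(size=n) + effect * y,
            "P2": rng.normal(size=n)})
        return vals, y

    def test_perfect_separator(self):
        vals, y = self.build(effect=20.0)
        params = nd.PanelParams(n_eval_iters=5, seed=0)
        report = nd.evaluate_panel(vals, y, ["P1"], params)
        assert report["mean_auc"] == 1.0
        assert report["youden_j"] == pytest.approx(1.0)

    def test_invariant_to_column_order_and_affine_rescale(self):
        vals, y = self.build()
        params = nd.PanelParams(n_eval_iters=5, seed=3)
        a = nd.evaluate_panel(vals, y, ["P1", "P2"], params)
        b = nd.evaluate_panel(vals[["P2", "P1"]], y, ["P2", "P1"], params)
        rescaled = vals.copy()
        rescaled["P1"] = 100.0 * rescaled["P1"] - 7.0
        c = nd.evaluate_panel(rescaled, y, ["P1", "P2"], params)
        assert a["mean_auc"] == pytest.approx(b["mean_auc"], abs=1e-9)
        assert a["mean_auc"] == pytest.approx(c["mean_auc"], abs=1e-6)

    def test_cross_disease_mode_uses_test_cohort(self):
        vals, y = self.build(seed=11)
        rng = np.random.default_rng(12)
        other_y = np.r_[np.ones(60), np.zeros(60)].astype(int)
        other = pd.DataFrame({"P1": rng.normal(size=120),
                              "P2": rng.normal(size=120)})
        params = nd.PanelParams(n_eval_iters=10, seed=4)
        self_report = nd.evaluate_panel(vals, y, ["P1"], params)
        cross_report = nd.evaluate_panel(vals, y, ["P1"], params,
                                         test_values=other,
                                         test_labels=other_y)
        assert self_report["mean_auc"] > 0.9
        assert abs(cross_report["mean_auc"] - 0.5) < 0.12
        assert cross_report["mode"] == "cross"

    def test_too_few_cases_rejected(self):
        vals, y = self.build(n=20)
        y = np.r_[np.ones(5), np.zeros(15)].astype(int)
        with pytest.raises(nd.DataError):
            nd.evaluate_panel(vals, y, ["P1"],
                              nd.PanelParams(n_eval_iters=1))


class TestLOSO:
    def test_weighted_mean_hand_example(self):
        assert nd.weighted_mean_auc([0.8, 0.6], [100, 300]) == \
            pytest.approx(0.65)

    def test_signal_cohort_beats_shuffled_site(self):
        rng = np.random.default_rng(13)
        n = 240
        sites = np.repeat(["SA", "SB", "SC", "SD"], n // 4)
        y = rng.integers(0, 2, size=n)
        vals = rng.normal(size=(n, 12))
        vals[:, 0] += 2.0 * y          # strong global signal
        vals[rng.random((n, 12)) < 0.05] = np.nan
        frame = pd.DataFrame(
            vals, index=[f"S{i}" for i in range(n)],
            columns=[f"P{i}" for i in range(12)])
        meta = pd.DataFrame({
            "sample_id": frame.index, "site": sites,
            "age": rng.uniform(55, 85, n),
            "sex": rng.choice(["F", "M"], n),
        }).set_index("sample_id", drop=False)
        params = nd.PanelParams(cv_folds=5, seed=2)
        report = nd.loso_evaluate(frame, meta, y, params)
        assert (report["per_site"]["auc"] > 0.8).all()
        lo = nd.weighted_mean_auc(report["per_site"]["auc"],
                                  report["per_site"]["n_test"])
        assert report["weighted_mean_auc"] == pytest.approx(lo)


class TestAUCProperties:
    """Property-based checks of the rank-based AUC."""

    from hypothesis import given, settings, strategies as hst

    @given(hst.lists(hst.tuples(hst.integers(0, 1),
                                hst.integers(-5, 5)),
                     min_size=4, max_size=80))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_matches_pairwise_counting_and_complement(self, pairs):
        labels = np.array([p[0] for p in pairs])
        scores = np.array([p[1] for p in pairs], dtype=float)
        if labels.sum() in (0, len(labels)):
            return
        auc = nd.roc_metrics(scores, labels)["auc"]
        assert auc == pytest.approx(brute_force_auc(scores, labels))
        flipped = nd.roc_metrics(-scores, labels)["auc"]
        assert auc == pytest.approx(1.0 - flipped)
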