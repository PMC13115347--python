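"""Metric oracles (brute force / reference implementations) and the
grouped statistical analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from dynfuse.stats import (analyze_results, classify_dominance, eta_squared,
                           gate_dominance, kruskal_wallis_eta2,
                           mann_whitney_delta, pr_auc, pr_baseline, roc_auc,
                           threshold_metrics)


def brute_force_auc(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(tie) over all pos/neg pairs."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_examples(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == 0.5
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_brute_force_on_random_instances(self, rng):
        """Rank formula == pairwise counting on 200 instances (with ties)."""
        for _ in range(200):
            n = rng.integers(4, 51)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.sum() == n:
                labels[0] = 0
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))
            expected = brute_force_auc(scores, labels)
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAuc:
    def test_random_baseline_equals_prevalence(self):
        labels = [1] * 13 + [0] * 61
        assert pr_baseline(labels) == pytest.approx(13 / 74)
        assert pr_baseline(labels) == pytest.approx(0.1757, abs=1e-4)
        assert round(pr_baseline(labels), 3) == 0.176

    def test_worked_examples(self):
        assert pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert pr_auc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.3).astype(int)
        labels[0] = 1
        a = pr_auc(scores, labels)
        b = pr_auc(np.exp(2 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.5, 0.6], [0, 0])


class TestThresholdMetrics:
    def test_perfect_separation(self):
        m = threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert all(v == 1.0 for v in m.values())

    def test_all_negative_predictions(self):
        m = threshold_metrics([0.1, 0.2, 0.3], [1, 0, 0])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["balanced_accuracy"] == 0.5

    def test_hand_computed_confusion(self):
        # TP=2 FP=1 FN=1 TN=6
        scores = [0.9, 0.8, 0.7, 0.2] + [0.1] * 6
        labels = [1, 1, 0, 1] + [0] * 6
        m = threshold_metrics(scores, labels)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["balanced_accuracy"] == pytest.approx((2 / 3 + 6 / 7) / 2)
        assert m["balanced_accuracy"] == pytest.approx(0.7619, abs=1e-4)

    def test_ties_at_threshold_count_positive(self):
        m = threshold_metrics([0.5, 0.5], [1, 0])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_undefined_f1_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="F1"):
            m = threshold_metrics([0.1, 0.1], [0, 0])
        assert m["f1"] == 0.0


class TestKruskalWallis:
    @pytest.mark.parametrize("h,expected", [
        (86.28, 0.679), (101.99, 0.803), (0.89, 0.007),
        (25.73, 0.203), (19.58, 0.154), (16.08, 0.127)])
    def test_effect_size_worked_examples(self, h, expected):
        """eta^2 = H/(N-1) with the per-cell N=128 reproduces the printed
        effect sizes from the printed H values."""
        assert round(eta_squared(h, 128), 3) == expected

    def test_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(25):
            groups = [rng.normal(loc=rng.normal(), size=rng.integers(5, 20))
                      for _ in range(rng.integers(2, 5))]
            h, p, _ = kruskal_wallis_eta2(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        groups = [np.round(rng.normal(size=30), 1) for _ in range(4)]
        h, p, _ = kruskal_wallis_eta2(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-9)

    def test_identical_groups_null(self):
        g = np.arange(10.0)
        h, p, eta2 = kruskal_wallis_eta2([g, g + 0.0, g.copy()])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_total_n_flag(self, rng):
        groups = [rng.normal(size=128) for _ in range(4)]
        h, _, eta_cell = kruskal_wallis_eta2(groups, n_cell=128)
        _, _, eta_total = kruskal_wallis_eta2(groups, use_total_n=True)
        assert eta_cell == pytest.approx(h / 127)
        assert eta_total == pytest.approx(h / 511)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_eta2([[1.0, 2.0], []])


class TestMannWhitney:
    def test_identical_samples(self):
        u, p, delta = mann_whitney_delta([1, 2, 3], [1, 2, 3])
        assert delta == 0.0
        assert p > 0.9

    def test_clear_shift_is_significant(self, rng):
        a = rng.normal(loc=1.0, size=50)
        b = rng.normal(loc=0.0, size=50)
        _, p, delta = mann_whitney_delta(a, b)
        assert p < 0.01
        assert delta > 0.5

    def test_u_convention_brute_force(self):
        """U counts a>b pairs: all of [1,2] below all of [3,4] gives U=0."""
        u, _, delta = mann_whitney_delta([1, 2], [3, 4])
        assert u == 0.0
        assert delta == -2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_delta([], [1.0])


class TestGateDominance:
    def test_symmetric_gate_is_balanced(self):
        delta, t, p, klass = gate_dominance([0.5] * 10)
        assert delta == 0.0 and t == 0.0 and p == 1.0
        assert klass == "balanced"

    def test_saturated_gate_reports_p_floor(self):
        delta, t, p, klass = gate_dominance([0.9] * 8)
        assert delta == pytest.approx(0.8)
        assert np.isinf(t) and t > 0
        assert p == 0.0
        assert klass == "strong_semantic"

    def test_moderate_and_reversal_classes(self, rng):
        g = 0.6 + 0.02 * rng.normal(size=40)
        delta, _, p, klass = gate_dominance(g)
        assert 0 < delta <= 0.5 and p < 0.05 and klass == "moderate_semantic"
        delta, _, p, klass = gate_dominance(1 - g)
        assert delta < 0 and p < 0.05 and klass == "reversal"

    def test_class_thresholds(self):
        assert classify_dominance(0.8, 0.001) == "strong_semantic"
        assert classify_dominance(0.3, 0.001) == "moderate_semantic"
        assert classify_dominance(0.8, 0.5) == "balanced"
        assert classify_dominance(-0.2, 0.001) == "reversal"

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            gate_dominance([0.7])


class TestMetricDivergence:
    def test_equal_auc_unequal_pr_auc_fixture(self):
        """Two rankings of the same labels: positives at depth {1,4} vs
        {2,3} of 8 tie at AUC 10/12 but differ in early precision."""
        scores = np.arange(8, 0, -1.0)
        labels_a = np.array([1, 0, 0, 1, 0, 0, 0, 0])
        labels_b = np.array([0, 1, 1, 0, 0, 0, 0, 0])
        assert roc_auc(scores, labels_a) == pytest.approx(
            roc_auc(scores, labels_b), abs=1e-9)
        ap_a = pr_auc(scores, labels_a)
        ap_b = pr_auc(scores, labels_b)
        assert ap_a == pytest.approx(0.75)
        assert ap_b == pytest.approx(7 / 12)
        assert abs(ap_a - ap_b) > 0.1


def _fake_results(rng, n_folds=3):
    from dynfuse.grid import enumerate_conditions
    rows = []
    for cond in enumerate_conditions():
        # plant a small attention advantage at the audio position
        base = 0.7 + 0.04 * (cond.audio_fusion == "attention") \
            + 0.01 * cond.pt_visual
        for fold in range(n_folds):
            rows.append({"condition_id": cond.condition_id, "fold_id": fold,
                         "seed": 0, "auc": base + 0.02 * rng.normal(),
                         "pr_auc": base - 0.15 + 0.02 * rng.normal(),
                         "gate_delta_vis": np.nan, **cond.group_labels()})
    return pd.DataFrame(rows)


class TestAnalyzeResults:
    def test_report_shapes_and_recovered_effect(self, rng):
        results = _fake_results(rng)
        gates = pd.DataFrame({
            "condition_id": ["c000"] * 6, "seed": 0, "fold_id": 0,
            "subject_id": [f"S{i}" for i in range(6)],
            "gate_mean": 0.8 + 0.02 * rng.normal(size=6)})
        report = analyze_results(results, gates=gates)
        tab = report.fusion_tables["auc"]
        assert set(tab["position"]) == {"vis_fusion", "audio_fusion",
                                        "text_fusion"}
        assert (tab["n"] == 128).all()  # 128 conditions per strategy/position
        audio = tab[tab.position == "audio_fusion"]
        best = audio.loc[audio["mean"].idxmax(), "strategy"]
        assert best == "attention"
        assert (audio["p"] < 0.001).all()
        pt = report.pretrain_table.set_index("modality")
        assert pt.loc["visual_semantic", "delta"] > 0
        assert {"visual_semantic", "audio", "text", "all3"} == set(pt.index)
        assert report.gate_table.iloc[0]["class"] == "strong_semantic"
        parsed = report.to_dict()
        assert set(parsed) == {"fusion", "pretraining", "gates"}

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            analyze_results(pd.DataFrame())
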