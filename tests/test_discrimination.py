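"""ROC/AUROC, bootstrap, threshold and efficiency-curve tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewscompare.discrimination import (
    DegenerateLabelsError,
    auroc,
    bootstrap_compare,
    efficiency_curve,
    efficiency_delta,
    roc_curve,
    stratified_report,
    threshold_metrics,
)
from ewscompare.synthetic import simulate_binormal_scores

from ._oracle import brute_force_concordance


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_tie_adjustment(self):
        assert auroc([1, 2, 2, 3], [0, 1, 0, 1]) == 0.875

    def test_all_tied_scores_give_half(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_error_names_class(self):
        with pytest.raises(DegenerateLabelsError, match="positive"):
            auroc([1, 2], [0, 0])
        with pytest.raises(DegenerateLabelsError, match="negative"):
            auroc([1, 2], [1, 1])

    def test_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 16, size=n)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert abs(auroc(scores, labels)
                       - brute_force_concordance(scores, labels)) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.integers(0, 15, size=500)
        labels = rng.random(500) < 0.2
        assert abs(auroc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 12, size=300)
        labels = rng.random(300) < 0.3
        assert auroc(scores, labels) == auroc(scores + 7, labels)


class TestRocCurve:
    def test_monotone_and_trapezoid_equals_concordance(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 16, size=400)
        labels = rng.random(400) < 0.25
        rc = roc_curve(scores, labels)
        assert (np.diff(rc.sensitivity) >= -1e-12).all()  # thresholds descend
        assert (np.diff(rc.specificity) <= 1e-12).all()
        assert rc.thresholds[0] == np.inf
        assert abs(rc.auroc - auroc(scores, labels)) < 1e-12


class TestBootstrapCompare:
    def test_identical_scores_give_exact_zero_difference(self):
        rng = np.random.default_rng(2)
        s = rng.integers(0, 10, 200)
        y = rng.random(200) < 0.3
        cmp = bootstrap_compare(s, s, y, n_boot=50, seed=1)
        assert cmp.diff_mean == 0.0
        assert cmp.diff_ci == (0.0, 0.0)
        assert not cmp.significant

    def test_single_replicate_boundary(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100)
        y = rng.random(100) < 0.4
        cmp = bootstrap_compare(s, s + rng.normal(size=100), y, n_boot=1, seed=0)
        assert cmp.n_boot == 1
        assert cmp.diff_ci[0] == cmp.diff_ci[1]

    def test_known_separation_detected(self):
        """Paired scores engineered for true AUROCs 0.90 vs 0.85."""
        rng = np.random.default_rng(42)
        n = 20_000
        mu = 1.8124  # Phi(mu/sqrt(2)) = 0.90
        y = np.zeros(n, bool)
        y[: n // 2] = True
        latent = rng.normal(0, 1, n) + mu * y
        sigma_b = 0.7274  # Phi(mu/sqrt(2(1+sigma^2))) = 0.85
        a = latent
        b = latent + rng.normal(0, sigma_b, n)
        cmp = bootstrap_compare(a, b, y, n_boot=300, seed=9)
        assert cmp.diff_ci[0] > 0 and cmp.significant
        assert abs(cmp.auroc_a - 0.90) < 0.01
        assert abs(cmp.auroc_b - 0.85) < 0.01

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=150)
        b = a + rng.normal(size=150)
        y = rng.random(150) < 0.3
        c1 = bootstrap_compare(a, b, y, n_boot=100, seed=5)
        c2 = bootstrap_compare(a, b, y, n_boot=100, seed=5)
        assert c1 == c2

    def test_cluster_bootstrap_runs(self):
        rng = np.random.default_rng(1)
        n = 300
        clusters = rng.integers(0, 40, n)
        a = rng.normal(size=n)
        y = rng.random(n) < 0.3
        cmp = bootstrap_compare(a, a + rng.normal(size=n), y, n_boot=50,
                                seed=3, cluster_ids=clusters)
        assert 0 <= cmp.auroc_a <= 1

    def test_degenerate_redraw_cap(self):
        # one positive in tiny data: many replicates degenerate; cap enforced
        s = np.array([1.0, 2.0, 3.0])
        y = np.array([False, False, True])
        with pytest.raises(DegenerateLabelsError):
            bootstrap_compare(s, s + 1, y, n_boot=2000, seed=0,
                              max_redraw_rounds=1)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        scores = [7] * 5 + [0] * 5
        labels = [1] * 5 + [0] * 5
        (m,) = threshold_metrics(scores, labels, thresholds=[5])
        assert (m.sensitivity, m.specificity, m.ppv) == (100.0, 100.0, 100.0)

    def test_two_by_two_arithmetic(self):
        # TP 9, FN 1, FP 90, TN 900
        scores = [5] * 9 + [0] * 1 + [5] * 90 + [0] * 900
        labels = [1] * 10 + [0] * 990
        (m,) = threshold_metrics(scores, labels, thresholds=[5])
        assert round(m.sensitivity, 1) == 90.0
        assert round(m.specificity, 1) == 90.9
        assert round(m.ppv, 1) == 9.1

    def test_ppv_prevalence_identity(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 15, 2000)
        labels = rng.random(2000) < 0.05
        prev = labels.mean()
        for m in threshold_metrics(scores, labels, thresholds=[3, 5, 7]):
            sens, spec = m.sensitivity, m.specificity
            expected = 100 * (sens * prev) / (sens * prev + (100 - spec) * (1 - prev))
            assert m.ppv == pytest.approx(expected, abs=1e-9)

    def test_threshold_above_max_score(self):
        scores = [0, 1, 2, 3]
        labels = [0, 0, 1, 1]
        with pytest.warns(UserWarning, match="PPV undefined"):
            (m,) = threshold_metrics(scores, labels, thresholds=[10])
        assert m.sensitivity == 0.0 and m.specificity == 100.0
        assert np.isnan(m.ppv)


class TestEfficiencyCurve:
    def test_threshold_zero_is_full_workload(self):
        eff = efficiency_curve([0, 5, 5, 7], [0, 0, 1, 1])
        row0 = eff[eff["threshold"] == 0].iloc[0]
        assert row0["workload"] == 1.0 and row0["sensitivity"] == 1.0

    def test_worked_example(self):
        eff = efficiency_curve([0, 5, 5, 7], [0, 0, 1, 1])
        row = eff[eff["threshold"] == 5].iloc[0]
        assert row["workload"] == 0.75 and row["sensitivity"] == 1.0
        last = eff.iloc[-1]
        assert last["threshold"] == 8 and last["workload"] == 0.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 14, 500)
        labels = rng.random(500) < 0.2
        eff = efficiency_curve(scores, labels)
        assert (np.diff(eff["workload"]) <= 0).all()
        assert (np.diff(eff["sensitivity"]) <= 0).all()

    def test_delta_between_systems(self):
        a = efficiency_curve([5, 5, 7, 0], [1, 1, 1, 0])
        b = efficiency_curve([4, 5, 7, 0], [1, 1, 1, 0])
        d = efficiency_delta(a, b, thresholds=[5])
        assert d.iloc[0]["workload_delta"] == pytest.approx(-0.25)


def _toy_table(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    sev = rng.normal(size=n)
    y = rng.random(n) < 1 / (1 + np.exp(-(sev * 2 - 3)))
    news = np.clip(np.round(4 + 2 * sev + rng.normal(0, 1, n)), 0, 20)
    groups = rng.integers(0, 3, n)
    return pd.DataFrame(
        {
            "hospital_id": np.where(rng.random(n) < 0.5, "PH", "JR"),
            "news": news.astype(int),
            "news2": np.clip(news + rng.integers(-1, 2, n), 0, 20).astype(int),
            "documented_t2rf": groups == 0,
            "at_risk_t2rf": groups == 1,
            "not_at_risk": groups == 2,
            "death24": y,
            "icu24": rng.random(n) < 0.02,
            "arrest24": rng.random(n) < 0.01,
        }
    ).assign(composite24=lambda d: d.death24 | d.icu24 | d.arrest24)


class TestStratifiedReport:
    def test_structure_and_low_event_flag(self):
        table = _toy_table()
        a_tab, t_tab = stratified_report(table, "risk_group", n_boot=50, seed=1)
        assert set(a_tab["stratum"]) == {
            "documented_t2rf", "at_risk_t2rf", "not_at_risk"
        }
        assert set(a_tab["endpoint"]) == {"death24", "icu24", "arrest24",
                                          "composite24"}
        # flag agrees with the event count rule
        assert (a_tab["low_events"] == (a_tab["n_events"] < 100)).all()
        # threshold table: 2 systems x 2 thresholds per cell
        cell = t_tab[(t_tab["stratum"] == "not_at_risk")
                     & (t_tab["endpoint"] == "death24")]
        assert len(cell) == 4

    def test_single_hospital_stratification(self):
        table = _toy_table()
        table["hospital_id"] = "PH"
        a_tab, _ = stratified_report(table, "hospital_id", n_boot=20, seed=2)
        assert set(a_tab["stratum"]) == {"PH"}
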