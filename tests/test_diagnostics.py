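"""Confusion metrics, ROC/AUC, DeLong variance and paired comparison."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from romap.diagnostics import (
    AucComparison,
    ConfusionTable,
    auc,
    confusion_at_cutoff,
    delong_compare,
    delong_variance,
    metrics,
    roc_analysis,
    roc_curve,
    select_cutoff,
)


def pair_count_auc(scores, labels):
    """Exhaustive pair-count oracle: P(pos > neg) with ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_counts(self):
        t = confusion_at_cutoff([90, 10], [True, False], 23.5)
        assert (t.tp, t.fp, t.tn, t.fn) == (1, 0, 1, 0)

    def test_single_class_degenerate(self):
        t = confusion_at_cutoff([90, 80], [True, True], 23.5)
        assert (t.fp, t.tn) == (0, 0) and t.tp == 2

    def test_matches_bruteforce_count(self, rng):
        scores = rng.uniform(0, 100, 100)
        labels = rng.random(100) < 0.4
        cutoff = 37.0
        t = confusion_at_cutoff(scores, labels, cutoff)
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= cutoff)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= cutoff)
        fn = sum(1 for s, l in zip(scores, labels) if l and s < cutoff)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s < cutoff)
        assert (t.tp, t.fp, t.tn, t.fn) == (tp, fp, tn, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1, 2], [True], 0.5)


class TestMetrics:
    def test_perfect_table(self):
        m = metrics(ConfusionTable(tp=10, fp=0, tn=5, fn=0))
        assert m["sensitivity"] == 100 and m["specificity"] == 100

    def test_hand_arithmetic(self):
        m = metrics(ConfusionTable(tp=3, fn=1, tn=8, fp=2))
        assert m["sensitivity"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["ppv"] == pytest.approx(60.0)
        assert m["npv"] == pytest.approx(100 * 8 / 9)

    def test_undefined_is_nan_not_zero(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = metrics(ConfusionTable(tp=0, fn=0, tn=3, fp=1))
        assert math.isnan(m["sensitivity"]) and not math.isnan(m["specificity"])

    def test_duplication_invariance(self, rng):
        t = ConfusionTable(tp=7, fp=3, tn=11, fn=2)
        doubled = ConfusionTable(tp=14, fp=6, tn=22, fn=4)
        assert metrics(t) == metrics(doubled)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_curve([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert (0.0, 1.0) in r.points
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_curve([5, 5, 5, 5], [1, 0, 1, 0])
        assert r.auc == pytest.approx(0.5)
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)

    def test_curve_monotone_and_anchored(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        pts = np.array(roc_curve(scores, labels).points)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_auc_equals_pair_count_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc_curve(scores, labels)
            assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
            assert auc(r) == pytest.approx(r.auc, abs=1e-12)

    def test_sign_reversal_flips_auc(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15), np.zeros(15)].astype(bool)
        assert roc_curve(-scores, labels).auc == pytest.approx(
            1 - roc_curve(scores, labels).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])


# independent oracle values computed with R pROC (DeLong) on this fixed
# dataset; synthetic scores, not patient data
POS_A = [0.7601, 1.5269, 2.4952, 0.3769, 3.0808, 1.8576, 1.4068, 1.5374,
         -0.3096, -0.678, -0.217, 0.2234, 3.3463, -0.2078, 0.5059]
NEG_A = [-1.7631, 0.7127, 0.6243, -0.0003, -1.4687, -0.3254, -0.7545,
         -0.9627, -0.6202, 1.1206, 2.04, 0.5644, -0.7944, 0.4301, 0.4663]
POS_B = [2.5822, 0.2198, 1.3876, 0.4231, 1.5458, 0.9542, 1.6084, 0.5786,
         -0.6697, 0.1514, -0.007, -0.6247, 1.1973, 1.1093, 0.5165]
NEG_B = [-1.3707, 0.8051, 1.1874, 0.2772, 2.347, 0.0439, 1.9981, -0.2043,
         -0.4659, -0.8899, 1.1744, -0.0869, -0.7058, 1.2394, -0.8117]
LAB_AB = [True] * 15 + [False] * 15


class TestDeLong:
    def test_matches_proc_reference_values(self):
        d = delong_variance(POS_A + NEG_A, LAB_AB)
        assert d["auc"] == pytest.approx(0.7377777778, abs=1e-9)
        assert d["se_auc"] == pytest.approx(0.0924523806, abs=1e-9)
        assert d["ci_auc"][0] == pytest.approx(0.5565744415, abs=1e-8)
        assert d["ci_auc"][1] == pytest.approx(0.9189811141, abs=1e-8)

    def test_paired_comparison_matches_proc(self):
        c = delong_compare(POS_A + NEG_A, POS_B + NEG_B, LAB_AB)
        assert c.auc_b == pytest.approx(0.64, abs=1e-9)
        assert c.z == pytest.approx(0.8365736081, abs=1e-8)
        assert c.p == pytest.approx(0.4028322856, abs=1e-8)

    def test_perfect_separation_zero_se(self):
        scores = list(range(20))
        labels = [False] * 10 + [True] * 10
        d = delong_variance(scores, labels)
        assert d["auc"] == 1.0 and d["se_auc"] == 0.0
        assert 0 <= d["ci_auc"][0] <= d["ci_auc"][1] <= 1

    def test_ci_within_unit_interval(self, rng):
        for _ in range(20):
            scores = rng.normal(size=12)
            labels = np.r_[np.ones(6), np.zeros(6)].astype(bool)
            d = delong_variance(scores, labels)
            lo, hi = d["ci_auc"]
            assert 0 <= lo <= d["auc"] <= hi <= 1

    def test_se_tracks_monte_carlo_sd(self, rng):
        """Estimated SE within 15% of the empirical SD of the AUC."""
        aucs, ses = [], []
        for _ in range(400):
            pos = rng.normal(1.0, 1.0, 30)
            neg = rng.normal(0.0, 1.0, 30)
            d = delong_variance(np.r_[pos, neg], np.r_[np.ones(30), np.zeros(30)].astype(bool))
            aucs.append(d["auc"])
            ses.append(d["se_auc"])
        assert np.mean(ses) == pytest.approx(np.std(aucs), rel=0.15)

    def test_identical_scores_give_null_comparison(self):
        s = POS_A + NEG_A
        c = delong_compare(s, s, LAB_AB)
        assert c.z == 0.0 and c.p == 1.0

    def test_antisymmetry(self):
        ab = delong_compare(POS_A + NEG_A, POS_B + NEG_B, LAB_AB)
        ba = delong_compare(POS_B + NEG_B, POS_A + NEG_A, LAB_AB)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)
        assert math.copysign(1, ab.z) == math.copysign(1, ab.auc_a - ab.auc_b)

    def test_perfect_vs_noise_marker(self, rng):
        labels = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        perfect = np.r_[np.arange(50) + 100.0, np.arange(50.0)]
        noise = rng.normal(size=100)
        assert delong_compare(perfect, noise, labels).p < 1e-6

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2, 3], [1, 2], [True, False, True])

    def test_roc_analysis_bundles_curve_and_ci(self):
        r = roc_analysis(POS_A + NEG_A, LAB_AB)
        assert r.points[0] == (0.0, 0.0)
        assert r.ci_auc[0] <= r.auc <= r.ci_auc[1]


class TestSelectCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        c = select_cutoff([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert c == pytest.approx(6.5)

    def test_maximizes_youden_j(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 15, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            c = select_cutoff(scores, labels)
            pos, neg = scores[labels], scores[~labels]

            def j(cut):
                return np.mean(pos >= cut) + np.mean(neg < cut) - 1

            best = max(j(t) for t in np.r_[scores - 0.5, scores + 0.5])
            assert j(c) == pytest.approx(best, abs=1e-12)

    def test_useless_marker_gives_zero_j(self):
        c = select_cutoff([5, 5, 5, 5], [1, 0, 1, 0])
        pos = neg = np.array([5.0, 5.0])
        assert np.mean(pos >= c) + np.mean(neg < c) - 1 == pytest.approx(0.0)
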