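import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amylometa as am

# Residue-level counts of ten published hot-spot predictors screened over a
# 33-protein amylome panel, with the performance figures reported alongside
# them: (TP, TN, FP, FN, sens%, spec%, Q%, MCC, F1). Values are printed with
# mixed rounding/truncation, so agreement is asserted to one unit in the last
# printed digit.
AMYLOME_PANEL = {
    "meta-predictor": (508, 5519, 1064, 740, "40.71", "83.84", "62.27", None, "0.36"),
    "Waltz": (710, 4300, 2273, 548, "56.43", "65.42", "60.93", "0.16", "0.33"),
    "PAFIG": (651, 4695, 1878, 607, "51.75", "71.43", "61.59", "0.18", "0.34"),
    "PASTA": (230, 6099, 484, 1018, "18.43", "92.65", "55.54", "0.14", "0.23"),
    "SALSA": (869, 3123, 3460, 379, "69.63", "47.44", "58.54", "0.13", "0.31"),
    "AGGRESCAN": (445, 5210, 1363, 813, "35.37", "79.26", "57.32", "0.13", "0.29"),
    "3D profile": (224, 5762, 821, 1024, "17.95", "87.53", "52.74", "0.06", "0.20"),
    "FoldAmyloid": (340, 5659, 924, 908, "27.24", "85.96", "56.60", "0.13", "0.27"),
    "TANGO": (172, 6282, 291, 1086, "13.67", "95.57", "54.62", "0.14", "0.20"),
    "AMYLPRED2": (478, 5512, 1071, 770, "38.30", "83.73", "61.02", "0.20", "0.34"),
}

# Peptide-level counts of the same ten predictors on 16 scrambled huntingtin
# N-terminal peptides (6 amyloid-forming, 10 not); these reproduce exactly at
# the printed precision.
HTT_PANEL = {
    "meta-predictor": (4, 10, 0, 2, "66.67", "100", "83.33", "0.75", "0.8"),
    "Waltz": (2, 10, 0, 4, "33.33", "100", "66.67", "0.49", "0.5"),
    "PAFIG": (5, 3, 7, 1, "83.33", "30", "56.67", "0.15", "0.56"),
    "PASTA": (5, 2, 8, 1, "83.33", "20", "51.67", "0.04", "0.53"),
    "SALSA": (5, 6, 4, 1, "83.33", "60", "71.67", "0.42", "0.67"),
    "AGGRESCAN": (6, 1, 9, 0, "100", "10", "55", "0.2", "0.57"),
    "3D profile": (4, 0, 10, 2, "66.67", "0", "33.33", "-0.49", "0.4"),
    "FoldAmyloid": (6, 1, 9, 0, "100", "10", "55", "0.2", "0.57"),
    "TANGO": (2, 7, 3, 4, "33.33", "70", "51.67", "0.03", "0.36"),
    "AMYLPRED2": (6, 5, 5, 0, "100", "50", "75", "0.52", "0.71"),
}


def _ulp(printed: str) -> float:
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 10.0**-decimals


def _assert_row(counts, printed, exact):
    cm = am.ConfusionMatrix(tp=counts[0], tn=counts[1], fp=counts[2], fn=counts[3])
    met = am.classification_metrics(cm)
    computed = {
        "sens": 100 * met.sensitivity,
        "spec": 100 * met.specificity,
        "q": 100 * met.q,
        "mcc": met.mcc,
        "f1": met.f1,
    }
    for value, key in zip(printed, ["sens", "spec", "q", "mcc", "f1"]):
        if value is None:
            continue
        tol = 1e-9 if exact else _ulp(value) + 1e-9
        assert round(computed[key], len(value.split(".")[1]) if "." in value else 0) == pytest.approx(
            float(value), abs=tol
        ), f"{key}: computed {computed[key]:.4f} vs reported {value}"


class TestClassificationMetrics:
    @pytest.mark.parametrize("predictor", list(HTT_PANEL))
    def test_htt_panel_rows_reproduce_exactly(self, predictor):
        row = HTT_PANEL[predictor]
        _assert_row(row[:4], row[4:], exact=True)

    @pytest.mark.parametrize("predictor", list(AMYLOME_PANEL))
    def test_amylome_panel_rows_reproduce(self, predictor):
        row = AMYLOME_PANEL[predictor]
        _assert_row(row[:4], row[4:], exact=False)

    def test_amylome_meta_predictor_mcc_recomputation(self):
        # the published figure 0.23 does not follow from its own counts; the
        # correct value from (508, 5519, 1064, 740) is 0.224
        cm = am.ConfusionMatrix(tp=508, tn=5519, fp=1064, fn=740)
        assert am.classification_metrics(cm).mcc == pytest.approx(0.2243, abs=5e-4)

    def test_perfect_classifier(self):
        met = am.classification_metrics(am.ConfusionMatrix(tp=7, tn=5, fp=0, fn=0))
        assert (met.acc, met.sensitivity, met.specificity, met.mcc, met.q, met.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_undefined_metrics_tagged(self):
        met = am.classification_metrics(am.ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(met.sensitivity) and "sensitivity" in met.undefined
        assert met.specificity == 1.0

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if min(tp + fn, tn + fp, tp + fp, tn + fn) == 0:
                continue
            a = am.classification_metrics(am.ConfusionMatrix(tp, tn, fp, fn)).mcc
            b = am.classification_metrics(am.ConfusionMatrix(tn, tp, fn, fp)).mcc
            assert a == pytest.approx(b)
            assert -1.0 <= a <= 1.0


class TestConfusionFromScores:
    def test_simple_split(self):
        cm = am.confusion_from_scores([0.9, 0.1], [1, 0], 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_threshold_above_max(self):
        cm = am.confusion_from_scores([0.9, 0.1], [1, 0], 2.0)
        assert (cm.tp, cm.fp) == (0, 0) and (cm.fn, cm.tn) == (1, 1)

    def test_tie_counts_positive(self):
        cm = am.confusion_from_scores([0.5, 0.5], [1, 0], 0.5)
        assert (cm.tp, cm.fp) == (1, 1)

    def test_matches_counting_oracle(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]  # both classes present
        thr = float(rng.random())
        cm = am.confusion_from_scores(scores, labels, thr)
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        assert cm.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="scores but"):
            am.confusion_from_scores([0.1], [1, 0], 0.5)


class TestROCAndAUC:
    def test_perfect_separation_passes_corner(self):
        roc = am.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))
        assert am.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_diagonal(self):
        roc = am.roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert am.auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_four_point_instance(self):
        scores, labels = [0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]
        # 3 of 4 positive-negative pairs are concordant
        assert am.auc(scores, labels) == pytest.approx(0.75)
        roc = am.roc_curve(scores, labels)
        # every distinct threshold's (sens, spec) appears on the curve
        for thr in [2.0, 0.9, 0.8, 0.3, 0.2]:
            cm = am.confusion_from_scores(scores, labels, thr)
            sens = cm.tp / (cm.tp + cm.fn)
            fpr = cm.fp / (cm.fp + cm.tn)
            assert any(
                abs(f - fpr) < 1e-12 and abs(t - sens) < 1e-12
                for f, t in zip(roc.fpr, roc.tpr)
            )

    def test_trapezoid_equals_concordance(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            assert abs(am.auc(scores, labels) - am.concordance_auc(scores, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            am.roc_curve([0.1, 0.2], [1, 1])


class TestPartialAUC:
    def test_full_band_equals_auc(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert am.partial_auc(scores, labels, 0.0, 1.0) == pytest.approx(
            am.auc(scores, labels), abs=1e-12
        )

    def test_perfect_classifier_band(self):
        assert am.partial_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.0, 0.2) == pytest.approx(0.2)

    def test_constant_scores_band(self):
        # triangle under the diagonal: 0.2^2 / 2
        assert am.partial_auc([0.5] * 6, [1, 0, 1, 0, 1, 0], 0.0, 0.2) == pytest.approx(0.02)

    def test_monotone_in_band_width_and_bounded(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        widths = [0.1, 0.2, 0.5, 0.8, 1.0]
        areas = [am.partial_auc(scores, labels, 0.0, w) for w in widths]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))
        assert areas[-1] <= am.auc(scores, labels) + 1e-12

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            am.partial_auc([0.1, 0.9], [0, 1], 0.5, 0.2)


class TestDeLong:
    def test_identical_scores(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:4] = [0, 0, 1, 1]
        res = am.delong_compare(s, s, y)
        assert res.diff == 0.0 and res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        a, b = rng.random(60), rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        r1 = am.delong_compare(a, b, y)
        r2 = am.delong_compare(b, a, y)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.diff == pytest.approx(-r2.diff)

    def test_auc_estimates_match_concordance(self, rng):
        a, b = rng.random(50), rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        res = am.delong_compare(a, b, y)
        assert res.auc_a == pytest.approx(am.concordance_auc(a, y), abs=1e-12)
        assert res.auc_b == pytest.approx(am.concordance_auc(b, y), abs=1e-12)

    def test_clearly_better_scorer_detected(self, rng):
        y = np.r_[np.ones(80), np.zeros(80)].astype(int)
        good = np.r_[rng.standard_normal(80) + 2.5, rng.standard_normal(80)]
        noise = rng.standard_normal(160)
        res = am.delong_compare(good, noise, y)
        assert res.diff > 0.2 and res.p_value < 1e-4


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        lo, hi = am.bootstrap_ci(lambda s_, y_: 0.42, s, y, n_boot=200, seed=1)
        assert lo == hi == 0.42

    def test_same_seed_reproducible(self, rng):
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        ci1 = am.bootstrap_ci(am.concordance_auc, s, y, n_boot=300, seed=9)
        ci2 = am.bootstrap_ci(am.concordance_auc, s, y, n_boot=300, seed=9)
        assert ci1 == ci2

    def test_auc_with_ci_brackets_estimate(self, rng):
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        s = np.r_[rng.standard_normal(50) + 1, rng.standard_normal(50)]
        for method in ("delong-variance", "bootstrap"):
            res = am.auc_with_ci(s, y, method=method, n_boot=300, seed=2)
            assert res.ci_low <= res.estimate <= res.ci_high
            assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_n_boot_minimum(self, rng):
        with pytest.raises(ValueError):
            am.bootstrap_ci(am.concordance_auc, [0.1, 0.9], [0, 1], n_boot=10)


def _exhaustive_best(scores, labels, objective):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best, best_thr = -np.inf, None
    for thr in sorted(set([np.inf, *scores]), reverse=True):
        cm = am.confusion_from_scores(scores, labels, thr)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        val = objective(sens, spec)
        if val > best + 1e-12:
            best, best_thr = val, thr
    return best_thr, best


class TestSelectThreshold:
    def test_perfect_separation(self):
        scores, labels = [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]
        for crit in ("upper-left", "youden"):
            thr = am.select_threshold(scores, labels, criterion=crit)
            cm = am.confusion_from_scores(scores, labels, thr)
            assert cm.fp == cm.fn == 0

    def test_youden_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            scores = rng.random(25)
            labels = rng.integers(0, 2, 25)
            labels[:2] = [0, 1]
            thr = am.select_threshold(scores, labels, criterion="youden")
            _, best = _exhaustive_best(scores, labels, lambda s, p: s + p - 1)
            cm = am.confusion_from_scores(scores, labels, thr)
            j = cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp) - 1
            assert j == pytest.approx(best, abs=1e-12)

    def test_upper_left_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            scores = rng.random(25)
            labels = rng.integers(0, 2, 25)
            labels[:2] = [0, 1]
            thr = am.select_threshold(scores, labels, criterion="upper-left")
            _, best = _exhaustive_best(
                scores, labels, lambda s, p: -math.hypot(1 - s, 1 - p)
            )
            cm = am.confusion_from_scores(scores, labels, thr)
            d = -math.hypot(1 - cm.tp / (cm.tp + cm.fn), 1 - cm.tn / (cm.tn + cm.fp))
            assert d == pytest.approx(best, abs=1e-12)

    def test_criteria_can_disagree_each_matches_its_optimum(self):
        # heavily imbalanced instance where J and corner distance differ
        scores = [0.95, 0.9, 0.85, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15, 0.1]
        labels = [1, 1, 1, 1, 1, 0, 1, 1, 1, 0, 0, 0]
        t_y = am.select_threshold(scores, labels, criterion="youden")
        t_u = am.select_threshold(scores, labels, criterion="upper-left")
        for crit, thr in [("youden", t_y), ("upper-left", t_u)]:
            obj = (
                (lambda s, p: s + p - 1)
                if crit == "youden"
                else (lambda s, p: -math.hypot(1 - s, 1 - p))
            )
            _, best = _exhaustive_best(scores, labels, obj)
            cm = am.confusion_from_scores(scores, labels, thr)
            got = obj(cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp))
            assert got == pytest.approx(best, abs=1e-12)

    def test_high_sensitivity_and_high_specificity(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        t_s = am.select_threshold(scores, labels, "high-sensitivity", target=0.9)
        cm = am.confusion_from_scores(scores, labels, t_s)
        assert cm.tp / (cm.tp + cm.fn) >= 0.9
        # no larger candidate threshold achieves the target
        larger = [s for s in scores if s > t_s]
        if larger:
            cm2 = am.confusion_from_scores(scores, labels, min(larger))
            assert cm2.tp / (cm2.tp + cm2.fn) < 0.9
        t_p = am.select_threshold(scores, labels, "high-specificity", target=0.9)
        cm3 = am.confusion_from_scores(scores, labels, t_p)
        assert cm3.tn / (cm3.tn + cm3.fp) >= 0.9

    def test_target_required(self):
        with pytest.raises(ValueError, match="target"):
            am.select_threshold([0.1, 0.9], [0, 1], "high-sensitivity")


class TestPerResidue:
    def test_overlapping_regions(self):
        pred = [am.RegionAnnotation("p", 1, 10)]
        truth = [am.RegionAnnotation("p", 6, 15)]
        cm = am.per_residue_confusion(pred, truth, 20)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 5, 5, 5)

    def test_no_predictions(self):
        cm = am.per_residue_confusion([], [am.RegionAnnotation("p", 6, 15)], 20)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 10, 10)

    def test_exact_match(self):
        r = [am.RegionAnnotation("p", 3, 9)]
        cm = am.per_residue_confusion(r, r, 12)
        assert cm.fp == cm.fn == 0 and cm.total == 12

    def test_counts_sum_to_length_and_batch_addition(self):
        cm1 = am.per_residue_confusion(
            [am.RegionAnnotation("a", 1, 5)], [am.RegionAnnotation("a", 2, 6)], 10
        )
        cm2 = am.per_residue_confusion(
            [am.RegionAnnotation("b", 4, 9)], [am.RegionAnnotation("b", 1, 3)], 15
        )
        assert (cm1 + cm2).total == 25

    @given(st.integers(6, 30), st.integers(1, 20), st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_region_splitting(self, seq_len, a, b):
        start, end = sorted([min(a, seq_len), min(b, seq_len)])
        start = max(start, 1)
        truth = [am.RegionAnnotation("p", 1, max(1, seq_len // 2))]
        whole = [am.RegionAnnotation("p", start, end)]
        if end > start:
            split = [
                am.RegionAnnotation("p", start, start),
                am.RegionAnnotation("p", start + 1, end),
            ]
        else:
            split = whole
        assert am.per_residue_confusion(whole, truth, seq_len) == am.per_residue_confusion(
            split, truth, seq_len
        )

    def test_out_of_bounds_region(self):
        with pytest.raises(ValueError, match="exceeds"):
            am.per_residue_confusion([am.RegionAnnotation("p", 1, 25)], [], 20)


class TestDeLongExternalCrossCheck:
    def test_matches_r_proc_reference(self, tmp_path, rng):
        """Dual-route check: the correlated-AUC test agrees with R's pROC
        implementation to high precision on a shared instance."""
        import shutil
        import subprocess

        y = np.r_[np.ones(30), np.zeros(40)].astype(int)
        a = rng.standard_normal(70) + y * 1.0
        b = 0.5 * a + rng.standard_normal(70) + y * 0.4
        res = am.delong_compare(a, b, y)
        data = tmp_path / "scores.tsv"
        np.savetxt(data, np.c_[y, a, b], delimiter="\t")
        script = (
            f'd<-read.table("{data}"); suppressMessages(library(pROC));'
            'ra<-roc(d$V1,d$V2,quiet=TRUE,direction="<");'
            'rb<-roc(d$V1,d$V3,quiet=TRUE,direction="<");'
            't<-roc.test(ra,rb,method="delong");'
            'cat(sprintf("%.12f %.12f %.12f", auc(ra), auc(rb), t$p.value))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        auc_a, auc_b, p = map(float, out)
        assert res.auc_a == pytest.approx(auc_a, abs=1e-10)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-9)
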