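import numpy as np
import pandas as pd
import pytest

from vidsleep import (
    ConfusionMatrix,
    cohen_kappa,
    compare_feature_sets,
    confusion,
    loocv,
    mann_whitney_u,
    metrics,
    roc_auc,
)
from vidsleep.classifier import SLEEP, WAKE, BayesianLDA
from vidsleep.evaluation import _subject_table
from vidsleep.exceptions import InvalidInputError, UndefinedMetricError
from vidsleep.features import EpochGrid

from oracles import metric_formulas, pairwise_auc


class TestConfusion:
    def test_perfect_agreement(self):
        labels = [WAKE] * 5 + [SLEEP] * 5
        cm = confusion(labels, labels)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 5)

    def test_all_sleep_prediction(self):
        truth = [WAKE] * 3 + [SLEEP] * 7
        cm = confusion([SLEEP] * 10, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 3, 7)

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 100))
            pred = np.where(rng.random(n) < 0.5, WAKE, SLEEP)
            truth = np.where(rng.random(n) < 0.3, WAKE, SLEEP)
            cm = confusion(pred, truth)
            tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
            for p, t in zip(pred, truth):
                key = ("t" if p == t else "f") + ("p" if p == WAKE else "n")
                tally[key] += 1
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
                tally["tp"], tally["fp"], tally["fn"], tally["tn"])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            confusion([WAKE], [WAKE, SLEEP])


class TestMetrics:
    def test_perfect_classifier(self):
        ms = metrics(ConfusionMatrix(5, 0, 0, 5))
        assert ms.precision == ms.sensitivity == ms.specificity == ms.accuracy == 1.0
        assert ms.kappa == 1.0

    def test_all_sleep_prediction_flags_precision(self):
        ms = metrics(ConfusionMatrix(0, 0, 3, 7))
        assert ms.accuracy == pytest.approx(0.7)
        assert ms.sensitivity == 0.0
        assert np.isnan(ms.precision)
        assert "precision" in ms.undefined

    def test_pooled_study_scale_cells(self):
        # cells at the scale of a pooled 1379-epoch evaluation
        ms = metrics(ConfusionMatrix(318, 35, 71, 955))
        assert ms.accuracy == pytest.approx(1273 / 1379)
        assert ms.accuracy == pytest.approx(0.9231, abs=5e-5)

    def test_matches_closed_forms_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 500, size=4)
            if tp + fp + fn + tn == 0:
                continue
            ms = metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            want = metric_formulas(int(tp), int(fp), int(fn), int(tn))
            for name, val in want.items():
                got = getattr(ms, name)
                assert (np.isnan(got) and np.isnan(val)) or got == val

    def test_empty_matrix_raises(self):
        with pytest.raises(InvalidInputError):
            metrics(ConfusionMatrix(0, 0, 0, 0))


class TestKappa:
    def test_perfect_and_chance(self):
        assert cohen_kappa(ConfusionMatrix(50, 0, 0, 50)) == 1.0
        assert cohen_kappa(ConfusionMatrix(50, 50, 0, 0)) == 0.0

    def test_study_scale_pooled_cells(self):
        assert cohen_kappa(ConfusionMatrix(318, 35, 71, 955)) == pytest.approx(0.8047, abs=5e-5)

    def test_degenerate_marginals_convention(self):
        # everything wake, predicted wake: p_e = 1 -> kappa 0 by convention
        assert cohen_kappa(ConfusionMatrix(10, 0, 0, 0)) == 0.0

    def test_kappa_one_iff_no_errors(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fp + fn + tn == 0 or (tp + fn == 0) or (fp + tn == 0):
                continue
            k = cohen_kappa(ConfusionMatrix(tp, fp, fn, tn))
            assert (k == 1.0) == (fp == 0 and fn == 0)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            pred = np.where(rng.random(n) < 0.4, WAKE, SLEEP)
            truth = np.where(rng.random(n) < 0.3, WAKE, SLEEP)
            if len(set(pred)) < 2 and len(set(truth)) < 2:
                continue
            assert cohen_kappa(confusion(pred, truth)) == pytest.approx(
                cohen_kappa_score(pred, truth), abs=1e-12)

    def test_permuted_truth_concentrates_near_zero(self):
        rng = np.random.default_rng(4)
        truth = np.where(rng.random(2000) < 0.3, WAKE, SLEEP)
        kappas = []
        for _ in range(30):
            perm = rng.permutation(truth)
            kappas.append(cohen_kappa(confusion(perm, truth)))
        assert abs(np.mean(kappas)) < 0.05


class TestRocAuc:
    def test_perfect_and_inverted(self):
        truth = np.array([WAKE, WAKE, SLEEP, SLEEP])
        _, a = roc_auc([1.0, 1.0, 0.0, 0.0], truth)
        assert a == 1.0
        _, a = roc_auc([0.0, 0.0, 1.0, 1.0], truth)
        assert a == 0.0

    def test_tie_handling_matches_pairwise_oracle(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.8, 0.8])
        y = np.array([0, 0, 1, 0, 1, 1])
        _, a = roc_auc(scores, y)
        assert a == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_random_scores_match_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            _, a = roc_auc(scores, y)
            assert a == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], np.array([1, 1]))

    def test_curve_schema(self):
        curve, _ = roc_auc([0.2, 0.7, 0.5], np.array([0, 1, 1]))
        assert list(curve.columns) == ["threshold", "fpr", "tpr"]


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        x = np.arange(30.0) % 5
        _, p = mann_whitney_u(x, x)
        assert p > 0.9

    def test_shifted_gaussians_highly_significant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.5, 1.0, 500)
        y = rng.normal(0.0, 1.0, 500)
        _, p = mann_whitney_u(x, y)
        assert p < 1e-4

    def test_empty_sample_raises(self):
        with pytest.raises(InvalidInputError):
            mann_whitney_u([], [1.0])


class TestLoocv:
    def test_each_subject_held_out_once(self, separable_cohort):
        rep = loocv(separable_cohort)
        assert sorted(rep.per_subject["subject"]) == sorted(separable_cohort)
        assert len(rep.per_subject) == len(separable_cohort)

    def test_separable_cohort_perfect_kappa(self, separable_cohort):
        rep = loocv(separable_cohort, feature_set="mact")
        assert (rep.per_subject["kappa"] == 1.0).all()
        assert rep.pooled_metrics.kappa == 1.0

    def test_pooled_confusion_sums_per_subject_cells(self, default_cohort):
        rep = loocv(default_cohort)
        cm = rep.pooled_confusion
        ps = rep.per_subject
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
            ps["tp"].sum(), ps["fp"].sum(), ps["fn"].sum(), ps["tn"].sum())
        assert cm.total == ps["n_epochs"].sum()

    def test_held_out_subject_cannot_influence_its_fold_model(self, default_cohort):
        """Training the fold model by hand on the other nine subjects
        must reproduce the report's confusion cells for the held-out one:
        its own data never reaches training."""
        rep = loocv(default_cohort)
        sid = "S01"
        grid = EpochGrid()
        tables = {
            s: _subject_table(r, grid, 95.0, 10.0, False)
            for s, r in default_cohort.items()
        }
        train = pd.concat([t for s, t in tables.items() if s != sid])
        train = train[train["binary"] != "excluded"]
        cols = ["mact_norm", "pslp_norm"]
        res = BayesianLDA(train[cols].to_numpy(), train["binary"].to_numpy()).fit()
        test = tables[sid]
        test = test[test["binary"] != "excluded"]
        p = np.atleast_1d(res.predict_proba(test[cols].to_numpy()))
        cm = confusion(np.where(p >= 0.5, WAKE, SLEEP), test["binary"].to_numpy())
        row = rep.per_subject.set_index("subject").loc[sid]
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (row["tp"], row["fp"], row["fn"], row["tn"])

    def test_two_subject_minimum(self, default_cohort):
        with pytest.raises(InvalidInputError):
            loocv({"only": next(iter(default_cohort.values()))})

    def test_unknown_feature_set(self, default_cohort):
        with pytest.raises(InvalidInputError):
            loocv(default_cohort, feature_set="bogus")

    def test_report_aggregation_and_summary(self, default_cohort):
        rep = loocv(default_cohort)
        agg = rep.aggregate().set_index("metric")
        assert 0.0 <= agg.loc["accuracy", "mean"] <= 1.0
        assert "Pooled confusion" in rep.summary()
        t2 = rep.per_subject_table()
        assert list(t2.columns) == ["subject", "n_epochs", "pct_wake", "accuracy", "kappa"]

    def test_feature_set_comparison_schema(self, default_cohort):
        tbl, reports = compare_feature_sets(default_cohort)
        assert list(tbl.columns) == ["mact", "pslp", "mact+pslp"]
        assert set(reports) == {"mact", "pslp", "mact+pslp"}
        assert {"TP", "FP", "FN", "TN", "kappa_mean", "pooled_auc"} <= set(tbl.index)
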