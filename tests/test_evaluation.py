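"""Regression metrics, confusion reports, and the cascade evaluation."""

import json

import numpy as np
import pytest

from prmlung import evaluation
from prmlung.evaluation import (
    ConfusionReport,
    confusion_from_labels,
    multiclass_accuracy,
    regression_metrics,
    run_full_evaluation,
)


class TestRegressionMetrics:
    def test_identity_prediction(self):
        y = np.array([0.3, 0.5, 0.9, 1.1])
        m = regression_metrics(y, y)
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == m.mse == m.rmse == 0.0
        assert m.spearman_rho == pytest.approx(1.0)

    def test_mean_predictor(self):
        m = regression_metrics([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert m.r2 == pytest.approx(0.0)
        assert m.mse == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(np.sqrt(2 / 3))

    def test_rmse_and_mae_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=30)
            p = y + rng.normal(scale=0.5, size=30)
            m = regression_metrics(y, p)
            assert m.rmse == pytest.approx(np.sqrt(m.mse), abs=1e-12)
            assert m.mae <= m.rmse + 1e-12
            assert -1.0 <= m.spearman_rho <= 1.0

    def test_negative_r2_for_bad_predictor(self):
        m = regression_metrics([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert m.r2 < 0

    def test_spearman_uses_average_ranks_for_ties(self):
        m = regression_metrics([1.0, 2.0, 2.0, 3.0], [10.0, 20.0, 20.0, 40.0])
        assert m.spearman_rho == pytest.approx(1.0)

    def test_zero_variance_truth_flags_r2(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = regression_metrics([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
        assert np.isnan(m.r2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [1.0, 2.0])  # n < 3
        with pytest.raises(ValueError):
            regression_metrics([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])

    def test_printed_rmse_consistency(self):
        """A reported MSE of 0.0030 implies an RMSE printing as 0.055."""
        rmse = float(np.sqrt(0.0030))
        assert round(rmse, 3) == 0.055


class TestConfusionReport:
    def test_metrics_recomputed_from_counts(self):
        r = ConfusionReport(tp=34, fn=6, tn=65, fp=7, positive_class="high_risk")
        assert r.sensitivity == pytest.approx(34 / 40)
        assert r.specificity == pytest.approx(65 / 72)
        assert r.ppv == pytest.approx(34 / 41)
        assert r.npv == pytest.approx(65 / 71)
        assert r.accuracy == pytest.approx(99 / 112)
        d = r.to_dict()
        assert d["sensitivity"]["numerator"] == 34
        assert d["sensitivity"]["denominator"] == 40
        assert d["sensitivity"]["percent"] == 85
        assert d["accuracy"]["percent"] == 88

    def test_zero_denominator_reports_none_never_zero(self):
        r = ConfusionReport(tp=0, fn=0, tn=5, fp=0)
        assert r.sensitivity is None
        assert r.ppv is None
        assert r.specificity == 1.0
        assert r.to_dict()["sensitivity"]["value"] is None

    def test_round_trip_through_dict(self):
        r = ConfusionReport(tp=8, fn=1, tn=112, fp=0, positive_class="copd")
        r2 = ConfusionReport.from_dict(json.loads(json.dumps(r.to_dict())))
        assert r2 == r

    def test_from_labels_counts(self):
        true = ["a", "a", "b", "b", "b"]
        pred = ["a", "b", "b", "b", "a"]
        r = confusion_from_labels(true, pred, positive="a")
        assert (r.tp, r.fn, r.tn, r.fp) == (1, 1, 2, 1)

    def test_all_correct_predictions(self):
        labels = ["x", "y", "x", "y"]
        r = confusion_from_labels(labels, labels, positive="x")
        assert r.fp == r.fn == 0
        assert r.accuracy == 1.0

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="not in declared set"):
            confusion_from_labels(["a", "b"], ["a", "c"], positive="a")


class TestMulticlassAccuracy:
    def test_four_of_nine(self):
        true = ["I"] * 4 + ["II"] * 3 + ["III", "IV"]
        pred = ["I", "I", "I", "I", "III", "III", "III", "II", "II"]
        acc, correct, total, table = multiclass_accuracy(true, pred)
        assert (correct, total) == (4, 9)
        assert round(100 * acc) == 44
        assert table.to_numpy().sum() == 9

    def test_perfect_agreement(self):
        acc, correct, total, _ = multiclass_accuracy(["II", "III"], ["II", "III"])
        assert acc == 1.0 and correct == total == 2

    def test_single_class_mismatch(self):
        acc, correct, _, _ = multiclass_accuracy(["I", "I"], ["II", "II"])
        assert acc == 0.0 and correct == 0


@pytest.fixture(scope="module")
def report(cohort_noisy):
    return run_full_evaluation(cohort_noisy, seed=42, families=("random_forest",))


class TestRunFullEvaluation:
    def test_discordant_count_equals_fp_plus_fn(self, report):
        nh = report.normal_highrisk_report
        assert len(report.discordant) == nh.fp + nh.fn

    def test_discordant_rows_carry_prm_context(self, report):
        assert {"prm_whole_lung_fsad_pct", "prm_whole_lung_emph_pct",
                "group_by_pft", "group_by_model"} <= set(report.discordant.columns)
        if len(report.discordant):
            assert (report.discordant["group_by_pft"]
                    != report.discordant["group_by_model"]).all()

    def test_noiseless_cohort_nearly_discordance_free(self, cohort_noiseless):
        rep = run_full_evaluation(cohort_noiseless, seed=11, families=("random_forest",))
        nh = rep.normal_highrisk_report
        assert len(rep.discordant) == nh.fp + nh.fn
        assert len(rep.discordant) <= 2  # only razor-edge subjects may flip

    def test_confusion_metrics_match_stored_counts(self, report):
        for r in (report.copd_report, report.normal_highrisk_report):
            d = r.to_dict()
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
                num, den = d[name]["numerator"], d[name]["denominator"]
                if den:
                    assert d[name]["value"] == pytest.approx(num / den)

    def test_task_denominators(self, report, cohort_noisy):
        # COPD task covers the whole validation set
        assert report.copd_report.total == report.n_validation == 100
        # normal/high-risk task covers predicted-and-true non-COPD subjects
        assert report.normal_highrisk_report.total <= report.n_validation

    def test_gold_table_square_over_stages(self, report):
        if report.gold_total:
            assert report.gold_table.to_numpy().sum() == report.gold_total
            assert report.gold_accuracy == pytest.approx(
                report.gold_correct / report.gold_total
            )

    def test_report_serialization_round_trip(self, report, tmp_path):
        path = tmp_path / "report.json"
        report.to_json(path)
        reloaded = json.loads(path.read_text())
        assert reloaded == json.loads(report.to_json())
        rf = reloaded["regression"]["random_forest"]
        assert rf["fev1_fvc"]["rmse"] == pytest.approx(
            report.regression["random_forest"]["fev1_fvc"].rmse
        )

    def test_best_family_beats_or_ties_alternatives(self, cohort_noisy):
        rep = run_full_evaluation(cohort_noisy, seed=7)
        best = rep.best_family
        best_r2 = np.mean([m.r2 for m in rep.regression[best].values()])
        for fam, per in rep.regression.items():
            assert best_r2 >= np.mean([m.r2 for m in per.values()]) - 1e-12


def test_evaluation_with_explicit_split_sizes(cohort_noisy):
    rep = run_full_evaluation(
        cohort_noisy, seed=0, split_sizes=(400, 100), families=("random_forest",)
    )
    assert rep.n_train == 400 and rep.n_validation == 100
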