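"""Metric suite: regression scores, confusion reports, cascade evaluation.

Regression quality is summarized by R^2 (coefficient of determination,
``1 - SS_res / SS_tot``; negative when worse than the mean predictor), MAE,
MSE, RMSE and Spearman rank correlation.  Classification of a validation
cohort is evaluated in a cascade that mirrors how the staging rules consume
predicted spirometry:

1. COPD vs non-COPD from the predicted FEV1/FVC (obstruction cut at 0.7);
2. among subjects predicted *and* truly non-COPD, normal vs high-risk from
   the predicted FEV1% (normal cut at 0.95);
3. among truly obstructed subjects, GOLD stage agreement from the predicted
   FEV1%.

Confusion reports keep their integer counts so every derived metric
(sensitivity, specificity, PPV, NPV, accuracy) remains exactly recomputable;
ratios with a zero denominator are reported as not-applicable (None), never
as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import staging
from .models import FEATURE_COLUMNS, PFTRegressor, split_train_validation, train_regressor

__all__ = [
    "RegressionMetrics",
    "ConfusionReport",
    "EvaluationReport",
    "regression_metrics",
    "confusion_from_labels",
    "multiclass_accuracy",
    "run_full_evaluation",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """The five regression scores for one (model, target) pair.

    ``r2`` is NaN (not applicable) when the true targets have zero variance.
    """

    r2: float
    mae: float
    mse: float
    rmse: float
    spearman_rho: float
    spearman_p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rmse - np.sqrt(self.mse)) > 1e-12 * max(1.0, self.rmse):
            raise ValueError("rmse must equal sqrt(mse)")

    def to_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2, "mae": self.mae, "mse": self.mse, "rmse": self.rmse,
            "spearman_rho": self.spearman_rho, "spearman_p": self.spearman_p, "n": self.n,
        }


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """Compute the metric set from paired vectors (n >= 3, finite)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("inputs must be finite")
    mse = float(mean_squared_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        warnings.warn("y_true has zero variance; R^2 is not applicable", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        rho, p = (1.0, 0.0) if np.array_equal(y_true, y_pred) else (float("nan"), float("nan"))
    else:
        rho, p = stats.spearmanr(y_true, y_pred)
    return RegressionMetrics(
        r2=r2,
        mae=float(mean_absolute_error(y_true, y_pred)),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        spearman_rho=float(rho),
        spearman_p=float(p),
        n=int(y_true.size),
    )


@dataclass(frozen=True)
class ConfusionReport:
    """Binary confusion counts with the five derived metrics.

    Metrics are properties recomputed from the stored integer counts; each
    returns a fraction, or None when its denominator is zero.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str = "positive"

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    def to_dict(self) -> dict[str, Any]:
        """Counts plus each metric with numerator/denominator and rounded percent."""
        out: dict[str, Any] = {
            "positive_class": self.positive_class,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
        }
        parts = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "accuracy": (self.tp + self.tn, self.total),
        }
        for name, (num, den) in parts.items():
            value = self._ratio(num, den)
            out[name] = {
                "value": value,
                "numerator": num,
                "denominator": den,
                "percent": None if value is None else round(100 * value),
            }
        return out

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ConfusionReport":
        return cls(tp=d["tp"], fn=d["fn"], tn=d["tn"], fp=d["fp"],
                   positive_class=d.get("positive_class", "positive"))


def confusion_from_labels(
    y_true, y_pred, positive: str, classes: tuple[str, ...] | None = None
) -> ConfusionReport:
    """Binary confusion report from label vectors.

    ``classes`` declares the allowed label set (default: the labels present
    in ``y_true``); a prediction outside it is an input error.  Any label
    other than ``positive`` counts as negative.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    declared = set(classes) if classes is not None else set(y_true.tolist())
    declared.add(positive)
    unseen = set(y_pred.tolist()) - declared
    if unseen:
        raise ValueError(f"predicted labels {sorted(map(str, unseen))} not in declared set")
    t_pos = y_true == positive
    p_pos = y_pred == positive
    return ConfusionReport(
        tp=int((t_pos & p_pos).sum()),
        fn=int((t_pos & ~p_pos).sum()),
        tn=int((~t_pos & ~p_pos).sum()),
        fp=int((~t_pos & p_pos).sum()),
        positive_class=positive,
    )


def multiclass_accuracy(y_true, y_pred) -> tuple[float, int, int, pd.DataFrame]:
    """Overall accuracy plus a per-class confusion table.

    Returns ``(accuracy, n_correct, n_total, table)`` where ``table`` is a
    true-by-predicted count matrix over the union of observed classes.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    correct = int((y_true == y_pred).sum())
    total = int(y_true.size)
    acc = correct / total if total else float("nan")
    return acc, correct, total, table


@dataclass
class EvaluationReport:
    """Everything the cascade evaluation produces on one validation set."""

    regression: dict[str, dict[str, RegressionMetrics]]  # family -> target -> metrics
    best_family: str
    copd_report: ConfusionReport
    normal_highrisk_report: ConfusionReport
    gold_accuracy: float | None
    gold_correct: int
    gold_total: int
    gold_table: pd.DataFrame
    discordant: pd.DataFrame  # normal/high-risk disagreements with PRM context
    n_train: int
    n_validation: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "regression": {
                fam: {t: m.to_dict() for t, m in per.items()}
                for fam, per in self.regression.items()
            },
            "best_family": self.best_family,
            "copd_report": self.copd_report.to_dict(),
            "normal_highrisk_report": self.normal_highrisk_report.to_dict(),
            "gold": {
                "accuracy": self.gold_accuracy,
                "correct": self.gold_correct,
                "total": self.gold_total,
                "table": self.gold_table.to_dict(),
            },
            "discordant": self.discordant.to_dict(orient="records"),
            "n_train": self.n_train,
            "n_validation": self.n_validation,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_DISCORDANT_COLUMNS = [
    "subject", "prm_whole_lung_fsad_pct", "prm_whole_lung_emph_pct",
    "group_by_pft", "fev1_pct", "fev1_fvc", "fev1_pct_predicted", "group_by_model",
]


def run_full_evaluation(
    cohort: pd.DataFrame,
    seed: int = 0,
    split_sizes: tuple[int, int] | None = None,
    families: tuple[str, ...] = ("random_forest", "mlp"),
    fitted: dict[str, dict[str, PFTRegressor]] | None = None,
) -> EvaluationReport:
    """Split, train both families on both targets, and run the full cascade.

    ``fitted`` may supply pre-fitted models as ``{family: {target: model}}``,
    in which case training is skipped for those entries.  The family with
    the higher mean validation R^2 provides the predictions for the staging
    cascade (ties go to the random forest).
    """
    train, val = split_train_validation(cohort, seed=seed, sizes=split_sizes)
    X_val = val[FEATURE_COLUMNS]

    regression: dict[str, dict[str, RegressionMetrics]] = {}
    predictions: dict[str, dict[str, np.ndarray]] = {}
    for family in families:
        regression[family] = {}
        predictions[family] = {}
        for target in ("fev1_fvc", "fev1_pct"):
            model = (fitted or {}).get(family, {}).get(target)
            if model is None:
                model = train_regressor(train, target=target, family=family, seed=seed)
            pred = model.predict(X_val)
            predictions[family][target] = pred
            regression[family][target] = regression_metrics(val[target], pred)

    def _mean_r2(family: str) -> float:
        vals = [m.r2 for m in regression[family].values() if np.isfinite(m.r2)]
        return float(np.mean(vals)) if vals else -np.inf

    best_family = max(families, key=lambda f: (_mean_r2(f), f == "random_forest"))
    pred_fvc = predictions[best_family]["fev1_fvc"]
    pred_pct = predictions[best_family]["fev1_pct"]

    true_group = val["group"].to_numpy()
    pred_stage = staging.classify_table(pred_fvc, pred_pct)
    pred_group = pred_stage["group"].to_numpy()

    # task 1: COPD vs non-COPD on the whole validation set
    bin_true = np.where(true_group == "copd", "copd", "non_copd")
    bin_pred = np.where(pred_group == "copd", "copd", "non_copd")
    copd_report = confusion_from_labels(bin_true, bin_pred, positive="copd",
                                        classes=("copd", "non_copd"))

    # task 2: normal vs high-risk among predicted & truly non-COPD subjects
    sel = (pred_group != "copd") & (true_group != "copd")
    nh_true = true_group[sel]
    nh_pred = np.where(pred_pct[sel] >= staging.NORMAL_FEV1_PCT_CUT, "normal", "high_risk")
    nh_report = confusion_from_labels(nh_true, nh_pred, positive="high_risk",
                                      classes=("normal", "high_risk"))

    discordant_rows = val.loc[sel].loc[nh_true != nh_pred]
    discordant = pd.DataFrame({
        "subject": discordant_rows.index,
        "prm_whole_lung_fsad_pct": discordant_rows["prm_whole_lung_fsad_pct"].to_numpy(),
        "prm_whole_lung_emph_pct": discordant_rows["prm_whole_lung_emph_pct"].to_numpy(),
        "group_by_pft": nh_true[nh_true != nh_pred],
        "fev1_pct": discordant_rows["fev1_pct"].to_numpy(),
        "fev1_fvc": discordant_rows["fev1_fvc"].to_numpy(),
        "fev1_pct_predicted": pred_pct[sel][nh_true != nh_pred],
        "group_by_model": nh_pred[nh_true != nh_pred],
    }, columns=_DISCORDANT_COLUMNS)

    # task 3: GOLD stage agreement among truly obstructed subjects
    copd_sel = true_group == "copd"
    if copd_sel.any():
        true_stage = np.array(
            [staging.gold_stage(v).value for v in val.loc[copd_sel, "fev1_pct"]], dtype=object
        )
        pred_stage_copd = np.array(
            [staging.gold_stage(v).value for v in pred_pct[copd_sel]], dtype=object
        )
        gold_acc, gold_correct, gold_total, gold_table = multiclass_accuracy(
            true_stage, pred_stage_copd
        )
    else:
        gold_acc, gold_correct, gold_total = None, 0, 0
        gold_table = pd.DataFrame()

    return EvaluationReport(
        regression=regression,
        best_family=best_family,
        copd_report=copd_report,
        normal_highrisk_report=nh_report,
        gold_accuracy=gold_acc,
        gold_correct=gold_correct,
        gold_total=gold_total,
        gold_table=gold_table,
        discordant=discordant,
        n_train=len(train),
        n_validation=len(val),
    )
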