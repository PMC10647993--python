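"""Rule-based staging of subjects from pulmonary-function values.

Subjects are staged from two spirometry numbers, both handled as fractions:

* ``fev1_fvc`` - FEV1/FVC, the ratio of the one-second forced expiratory
  volume to the forced vital capacity; values below 0.7 define airflow
  obstruction (COPD).
* ``fev1_pct`` - FEV1 as a fraction of the value predicted for a matched
  healthy subject; it grades severity.

Rules
-----
* COPD iff ``fev1_fvc < 0.7``; severity by GOLD stage:
  I if ``fev1_pct >= 0.80``, II if ``0.50 <= fev1_pct < 0.80``,
  III if ``0.30 <= fev1_pct < 0.50``, IV if ``fev1_pct < 0.30``.
* Otherwise normal iff ``fev1_pct >= 0.95``, else high-risk.

Two edge conventions are fixed here: ``fev1_fvc`` exactly 0.7 is non-COPD
(GOLD's obstruction cut is strict), and *any* non-COPD subject below the
normal cut counts as high-risk, including ``fev1_pct < 0.80`` (the screening
definition of the high-risk band only names 0.80-0.95, but a non-COPD,
non-normal subject has nowhere else to go).

The same rule applied to model-predicted spirometry
(:func:`classify_from_predictions`) turns a pair of regression models into a
screening classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "GoldStage",
    "GroupLabel",
    "PFTValues",
    "gold_stage",
    "classify_group",
    "classify_from_predictions",
    "classify_table",
    "coerce_fraction",
]

COPD_FEV1_FVC_CUT = 0.70
NORMAL_FEV1_PCT_CUT = 0.95


class Group(str, Enum):
    NORMAL = "normal"
    HIGH_RISK = "high_risk"
    COPD = "copd"


class GoldStage(str, Enum):
    NONE = "none"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class PFTValues:
    """Spirometry pair, both as fractions (not percent)."""

    fev1_fvc: float
    fev1_pct: float

    def __post_init__(self) -> None:
        for name, v, hi in (("fev1_fvc", self.fev1_fvc, 1.2), ("fev1_pct", self.fev1_pct, 1.6)):
            if not np.isfinite(v) or v <= 0 or v > hi:
                raise ValueError(f"{name}={v!r} outside the valid domain (0, {hi}]")


@dataclass(frozen=True)
class GroupLabel:
    group: Group
    gold: GoldStage = GoldStage.NONE

    def __post_init__(self) -> None:
        if (self.gold is not GoldStage.NONE) != (self.group is Group.COPD):
            raise ValueError("GOLD stage is set iff the group is COPD")


def gold_stage(fev1_pct: float) -> GoldStage:
    """GOLD severity stage for an obstructed subject (``fev1_fvc < 0.7``)."""
    if fev1_pct >= 0.80:
        return GoldStage.I
    if fev1_pct >= 0.50:
        return GoldStage.II
    if fev1_pct >= 0.30:
        return GoldStage.III
    return GoldStage.IV


def classify_group(values: PFTValues | None = None, *, fev1_fvc: float | None = None,
                   fev1_pct: float | None = None) -> GroupLabel:
    """Stage a subject from measured spirometry.

    Accepts either a :class:`PFTValues` or the two fractions as keywords.
    """
    if values is None:
        values = PFTValues(fev1_fvc=float(fev1_fvc), fev1_pct=float(fev1_pct))
    if values.fev1_fvc < COPD_FEV1_FVC_CUT:
        return GroupLabel(Group.COPD, gold_stage(values.fev1_pct))
    if values.fev1_pct >= NORMAL_FEV1_PCT_CUT:
        return GroupLabel(Group.NORMAL)
    return GroupLabel(Group.HIGH_RISK)


def classify_from_predictions(pred_fev1_fvc: float, pred_fev1_pct: float) -> GroupLabel:
    """Stage a subject from model-predicted spirometry (same rule)."""
    return classify_group(PFTValues(fev1_fvc=float(pred_fev1_fvc), fev1_pct=float(pred_fev1_pct)))


def classify_table(
    fev1_fvc: np.ndarray | pd.Series, fev1_pct: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Vectorized staging; returns a frame with ``group`` and ``gold`` columns."""
    fvc = np.asarray(fev1_fvc, dtype=float)
    pct = np.asarray(fev1_pct, dtype=float)
    if fvc.shape != pct.shape:
        raise ValueError("fev1_fvc and fev1_pct must have the same length")
    copd = fvc < COPD_FEV1_FVC_CUT
    group = np.where(copd, Group.COPD.value,
                     np.where(pct >= NORMAL_FEV1_PCT_CUT, Group.NORMAL.value,
                              Group.HIGH_RISK.value))
    gold = np.full(fvc.shape, GoldStage.NONE.value, dtype=object)
    gold[copd & (pct >= 0.80)] = GoldStage.I.value
    gold[copd & (pct >= 0.50) & (pct < 0.80)] = GoldStage.II.value
    gold[copd & (pct >= 0.30) & (pct < 0.50)] = GoldStage.III.value
    gold[copd & (pct < 0.30)] = GoldStage.IV.value
    return pd.DataFrame({"group": group, "gold": gold})


def coerce_fraction(values: pd.Series, name: str = "") -> pd.Series:
    """Rescale a percent-scale spirometry column to fractions.

    Published tables mix scales (82.87 vs 0.83 for the same quantity); a
    column whose median exceeds 2 is taken to be in percent and divided by
    100, with a log record of the conversion.
    """
    values = pd.to_numeric(values)
    if values.median() > 2.0:
        logger.info("column %s looks percent-scaled (median %.3g); dividing by 100",
                    name or values.name, values.median())
        return values / 100.0
    return values
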