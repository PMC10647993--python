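"""Voxel-wise parametric response mapping (PRM) and regional aggregation.

PRM jointly thresholds the inspiratory and the registered expiratory CT
density of each lung voxel to label it as emphysema, functional small-airways
disease (fSAD), normal parenchyma, or uncategorized tissue:

===============  ==================  ==================
class            inspiratory HU      expiratory HU
===============  ==================  ==================
emphysema        <= -950             <= -856
fSAD             >  -950             <= -856
normal           >  -950             >  -856
uncategorized    <= -950             >  -856
===============  ==================  ==================

The two thresholds split the HU plane into four half-plane quadrants, so
classification is total: every finite (inspiratory, expiratory) pair receives
exactly one label.  Voxels exactly on a threshold go to the ``<=`` side; such
voxels are measure-zero in real CT data.

Labels and the regional parameter vector
----------------------------------------
Label maps are integer volumes on the inspiratory grid: 0 outside the lung
mask, then 1 = emphysema, 2 = fSAD, 3 = normal, 4 = uncategorized.

For each of 8 regions (whole lung, left lung, right lung and the five lobes)
nine quantities are reported: the region lung volume LV (mL), the four class
volumes (mL) and the four class percentages (% of region LV) - 72 regional
parameters in total, in a fixed, documented order (:func:`feature_names`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INSP_THRESHOLD_HU",
    "EXP_THRESHOLD_HU",
    "LABEL_OUTSIDE",
    "LABEL_EMPH",
    "LABEL_FSAD",
    "LABEL_NORMAL",
    "LABEL_UNCAT",
    "CLASS_NAMES",
    "REGIONS",
    "QUANTITIES",
    "PRMLabelMap",
    "PRMParameterVector",
    "classify_voxel",
    "classify_voxels",
    "compute_prm_map",
    "aggregate_regions",
    "feature_names",
]

INSP_THRESHOLD_HU: float = -950.0
EXP_THRESHOLD_HU: float = -856.0

LABEL_OUTSIDE = 0
LABEL_EMPH = 1
LABEL_FSAD = 2
LABEL_NORMAL = 3
LABEL_UNCAT = 4

#: class index -> short name, in label order 1..4
CLASS_NAMES = {
    LABEL_EMPH: "emph",
    LABEL_FSAD: "fsad",
    LABEL_NORMAL: "normal",
    LABEL_UNCAT: "uncat",
}

#: region key -> lobe labels it aggregates (lobes 1-3 right, 4-5 left)
REGIONS: dict[str, tuple[int, ...]] = {
    "whole_lung": (1, 2, 3, 4, 5),
    "left_lung": (4, 5),
    "right_lung": (1, 2, 3),
    "right_upper": (1,),
    "right_middle": (2,),
    "right_lower": (3,),
    "left_upper": (4,),
    "left_lower": (5,),
}

#: the nine per-region quantities, in reporting order
QUANTITIES = (
    "lv_ml",
    "emph_ml",
    "fsad_ml",
    "normal_ml",
    "uncat_ml",
    "emph_pct",
    "fsad_pct",
    "normal_pct",
    "uncat_pct",
)


def feature_names() -> list[str]:
    """The fixed order of the 72 regional PRM parameters.

    ``prm_<region>_<quantity>`` for the 8 regions of :data:`REGIONS` (in
    dict order) crossed with the 9 quantities of :data:`QUANTITIES`.
    """
    return [f"prm_{r}_{q}" for r in REGIONS for q in QUANTITIES]


@dataclass
class PRMLabelMap:
    """Per-voxel PRM class labels on the inspiratory grid.

    Attributes
    ----------
    labels : ndarray of int8
        0 outside the lung mask, 1-4 inside (see module docstring).
    spacing : tuple of float
        Voxel spacing in mm along each array axis.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, [0, 1, 2, 3, 4]).all():
            raise ValueError("label map contains values outside {0,1,2,3,4}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is in mm; 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def class_counts(self, mask: np.ndarray | None = None) -> dict[int, int]:
        lab = self.labels if mask is None else self.labels[mask]
        return {c: int((lab == c).sum()) for c in CLASS_NAMES}


@dataclass
class PRMParameterVector:
    """The 72 regional PRM parameters plus bookkeeping flags.

    ``values`` is a :class:`pandas.Series` indexed by :func:`feature_names`.
    Regions with zero lung volume report all percentages as 0 and are listed
    in ``empty_regions``.
    """

    values: pd.Series
    empty_regions: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])

    def to_frame(self) -> pd.DataFrame:
        return self.values.to_frame().T


def classify_voxel(insp_hu: float, exp_hu: float) -> int:
    """Classify a single voxel from its paired HU values.

    Returns one of the labels 1 (emphysema), 2 (fSAD), 3 (normal),
    4 (uncategorized).  Raises ``ValueError`` on non-finite input.
    """
    if not (np.isfinite(insp_hu) and np.isfinite(exp_hu)):
        raise ValueError("HU values must be finite")
    return int(
        classify_voxels(np.asarray([insp_hu], dtype=float), np.asarray([exp_hu], dtype=float))[0]
    )


def classify_voxels(insp_hu: np.ndarray, exp_hu: np.ndarray) -> np.ndarray:
    """Vectorized PRM classification of paired HU arrays.

    Parameters
    ----------
    insp_hu, exp_hu : ndarray
        Matching-shape arrays of inspiratory and (registered) expiratory HU.

    Returns
    -------
    ndarray of int8 with values in {1, 2, 3, 4}.
    """
    insp_hu = np.asarray(insp_hu, dtype=float)
    exp_hu = np.asarray(exp_hu, dtype=float)
    if insp_hu.shape != exp_hu.shape:
        raise ValueError("inspiratory and expiratory arrays must have the same shape")
    low_insp = insp_hu <= INSP_THRESHOLD_HU
    low_exp = exp_hu <= EXP_THRESHOLD_HU
    out = np.empty(insp_hu.shape, dtype=np.int8)
    out[low_insp & low_exp] = LABEL_EMPH
    out[~low_insp & low_exp] = LABEL_FSAD
    out[~low_insp & ~low_exp] = LABEL_NORMAL
    out[low_insp & ~low_exp] = LABEL_UNCAT
    return out


def compute_prm_map(
    insp: np.ndarray,
    exp_registered: np.ndarray,
    lung_mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    hu_validity_window: tuple[float, float] | None = None,
) -> PRMLabelMap:
    """Classify every in-mask voxel of a registered pair.

    Parameters
    ----------
    insp, exp_registered : ndarray
        Inspiratory volume and expiratory volume resampled onto the
        inspiratory grid, in HU.
    lung_mask : ndarray of bool
        Lung mask on the inspiratory grid.
    spacing : tuple of float
        Voxel spacing in mm.
    hu_validity_window : (low, high), optional
        If given, in-mask voxels whose *inspiratory* HU falls outside the
        window are dropped from the mask before classification (a crude
        airway/vessel exclusion).  Default: off, i.e. the bare threshold
        rule is applied to every masked voxel.
    """
    insp = np.asarray(insp, dtype=float)
    exp_registered = np.asarray(exp_registered, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not (insp.shape == exp_registered.shape == lung_mask.shape):
        raise ValueError(
            f"grid mismatch: insp {insp.shape}, exp {exp_registered.shape}, "
            f"mask {lung_mask.shape}"
        )
    mask = lung_mask
    if hu_validity_window is not None:
        lo, hi = hu_validity_window
        mask = mask & (insp >= lo) & (insp <= hi)
    # non-finite voxels (e.g. marked invalid by resampling) never classify
    mask = mask & np.isfinite(insp) & np.isfinite(exp_registered)
    labels = np.zeros(insp.shape, dtype=np.int8)
    labels[mask] = classify_voxels(insp[mask], exp_registered[mask])
    return PRMLabelMap(labels=labels, spacing=tuple(spacing))


def aggregate_regions(label_map: PRMLabelMap, lobe_mask: np.ndarray) -> PRMParameterVector:
    """Aggregate a PRM label map into the 72 regional parameters.

    Parameters
    ----------
    label_map : PRMLabelMap
    lobe_mask : ndarray of int
        Lobe labels on the same grid: 0 = background, 1-3 = right upper /
        middle / lower lobe, 4-5 = left upper / lower lobe.

    Notes
    -----
    Lung voxels not covered by any lobe label still count toward the
    whole-lung region (with a warning); lobe and left/right totals then fall
    short of the whole-lung total by exactly those voxels.
    """
    lobe_mask = np.asarray(lobe_mask)
    if lobe_mask.shape != label_map.labels.shape:
        raise ValueError("lobe mask shape does not match label map")
    labels = label_map.labels
    in_lung = labels > 0
    uncovered = int((in_lung & (lobe_mask == 0)).sum())
    if uncovered:
        warnings.warn(
            f"{uncovered} lung voxels are outside every lobe; they are counted "
            "in the whole-lung region only",
            stacklevel=2,
        )
    vox_ml = label_map.voxel_volume_ml

    # per-lobe per-class voxel counts via a 2D histogram over (lobe, class)
    counts = np.zeros((6, 5), dtype=np.int64)  # lobe 0..5 x class 0..4
    np.add.at(counts, (lobe_mask[in_lung].astype(np.int64), labels[in_lung].astype(np.int64)), 1)

    out: dict[str, float] = {}
    empty: list[str] = []
    for region, lobes in REGIONS.items():
        c = counts[list(lobes), :].sum(axis=0)
        if region == "whole_lung":
            c = c + counts[0, :]  # uncovered lung voxels
        total = int(c.sum())
        lv = total * vox_ml
        out[f"prm_{region}_lv_ml"] = lv
        for cls, name in CLASS_NAMES.items():
            out[f"prm_{region}_{name}_ml"] = c[cls] * vox_ml
        if total == 0:
            empty.append(region)
            for name in CLASS_NAMES.values():
                out[f"prm_{region}_{name}_pct"] = 0.0
        else:
            for cls, name in CLASS_NAMES.items():
                out[f"prm_{region}_{name}_pct"] = 100.0 * c[cls] / total
    series = pd.Series(out).reindex(feature_names())
    return PRMParameterVector(values=series, empty_regions=empty)
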