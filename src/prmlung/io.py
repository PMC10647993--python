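"""NIfTI and CSV input/output.

Volumes are written as NIfTI with a diagonal affine built from the voxel
spacing (mm); displacement fields as 4D NIfTI with the vector component on
the last axis.  Cohort tables are CSV in the fixed
:data:`prmlung.synthetic.COHORT_COLUMNS` order; on ingestion the two
spirometry columns are auto-rescaled from percent to fractions when needed
and rows with missing feature values are dropped (logged).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .models import FEATURE_COLUMNS
from .staging import coerce_fraction
from .synthetic import PhantomResult
from .volumes import DeformationField, PairedStudy

logger = logging.getLogger(__name__)

__all__ = [
    "save_volume", "load_volume", "save_field", "load_field",
    "write_phantom", "read_paired_study", "write_cohort", "read_cohort",
]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(path, data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_field(path, field: DeformationField, spacing=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(field.displacement.astype(np.float32), _affine(spacing)), str(path))


def load_field(path) -> DeformationField:
    img = nib.load(str(path))
    return DeformationField(np.asarray(img.dataobj, dtype=float))


_PHANTOM_FILES = {
    "insp": "insp.nii.gz",
    "exp": "exp.nii.gz",
    "lung_mask": "lung_mask.nii.gz",
    "lobe_mask": "lobe_mask.nii.gz",
    "prm_truth": "prm_truth.nii.gz",
    "true_alignment": "true_alignment.nii.gz",
}


def write_phantom(out_dir, result: PhantomResult) -> dict[str, Path]:
    """Write a generated phantom as NIfTI volumes; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = result.study
    paths = {k: out_dir / v for k, v in _PHANTOM_FILES.items()}
    save_volume(paths["insp"], st.insp, st.spacing)
    save_volume(paths["exp"], st.exp, st.spacing)
    save_volume(paths["lung_mask"], st.lung_mask, st.spacing)
    save_volume(paths["lobe_mask"], st.lobe_mask.astype(np.int16), st.spacing)
    save_volume(paths["prm_truth"], result.truth.labels.astype(np.int16), st.spacing)
    save_field(paths["true_alignment"], result.true_alignment, st.spacing)
    return paths


def read_paired_study(insp_path, exp_path, lung_mask_path, lobe_mask_path=None) -> PairedStudy:
    insp, spacing = load_volume(insp_path)
    exp, _ = load_volume(exp_path)
    lung, _ = load_volume(lung_mask_path)
    if lobe_mask_path is not None:
        lobes, _ = load_volume(lobe_mask_path)
        lobes = np.asarray(lobes).astype(np.int8)
    else:
        lobes = np.zeros(insp.shape, dtype=np.int8)
    return PairedStudy(
        insp=np.asarray(insp, dtype=float),
        exp=np.asarray(exp, dtype=float),
        lung_mask=np.asarray(lung) > 0,
        lobe_mask=lobes,
        spacing=spacing,
    )


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path, require_features: bool = True) -> pd.DataFrame:
    """Read a cohort CSV, normalizing spirometry scale and dropping bad rows."""
    df = pd.read_csv(path)
    for col in ("fev1_fvc", "fev1_pct"):
        if col in df.columns:
            df[col] = coerce_fraction(df[col], name=col)
    feature_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    if require_features:
        missing = sorted(set(FEATURE_COLUMNS) - set(df.columns))
        if missing:
            raise ValueError(f"cohort file lacks feature columns: {missing[:5]}...")
    bad = df[feature_cols].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d rows with missing feature values", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return df
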