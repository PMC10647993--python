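"""Synthetic paired-breath CT phantoms and spirometry cohorts.

The study population this package targets - a community LDCT screening
cohort with paired inspiratory/expiratory scans and spirometry - is not
publicly available, so every pipeline stage is exercised against synthetic
data with known ground truth:

* :func:`generate_phantom_pair` builds a paired-breath volume whose voxels
  carry a *known* PRM class.  Lung geometry is five disjoint axis-aligned
  ellipsoidal lobes (three right, two left).  Each in-mask voxel is assigned
  a class at the configured per-lobe fractions, then inspiratory and
  expiratory HU are drawn from class-specific intervals that keep a 1 HU
  guard band around the -950 / -856 thresholds, so a zero-noise,
  zero-warp phantom classifies back to its ground truth *exactly*.
  Optionally the expiratory volume is warped by a smooth random
  displacement field (what registration must undo) and Gaussian HU noise
  is added.
* :func:`generate_cohort` emits a feature table (72 regional PRM parameters
  + age/sex/height/weight) in which the two spirometry outcomes are a known
  linear function of whole-lung fSAD% and emphysema% plus Gaussian noise,
  so regression models have a recoverable generative truth.

HU intervals per class (guard-banded)
-------------------------------------
============== ==================== ====================
class          inspiratory          expiratory
============== ==================== ====================
emphysema      [-1000, -951]        [-1000, -857]
fSAD           [-949,  -700]        [-1000, -857]
normal         [-949,  -700]        [-855,  -600]
uncategorized  [-1000, -951]        [-855,  -600]
============== ==================== ====================

Within a phantom the HU texture is driven by one spatially smooth quantile
field shared by both phases, so aligned voxels are monotonically related in
intensity - giving deformable registration realistic structure to lock onto
while each voxel's HU stays uniform over its class interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from . import staging
from .prm import (
    CLASS_NAMES,
    LABEL_EMPH,
    LABEL_FSAD,
    LABEL_NORMAL,
    LABEL_UNCAT,
    PRMLabelMap,
    REGIONS,
    feature_names,
)
from .volumes import DeformationField, PairedStudy, apply_displacement, invert_displacement

__all__ = [
    "PhantomConfig",
    "PhantomResult",
    "CohortConfig",
    "generate_phantom_pair",
    "generate_cohort",
    "make_lobe_mask",
    "HU_INTERVALS",
    "BACKGROUND_HU",
    "COHORT_COLUMNS",
]

#: (inspiratory interval, expiratory interval) per PRM class, in HU
HU_INTERVALS: dict[int, tuple[tuple[float, float], tuple[float, float]]] = {
    LABEL_EMPH: ((-1000.0, -951.0), (-1000.0, -857.0)),
    LABEL_FSAD: ((-949.0, -700.0), (-1000.0, -857.0)),
    LABEL_NORMAL: ((-949.0, -700.0), (-855.0, -600.0)),
    LABEL_UNCAT: ((-1000.0, -951.0), (-855.0, -600.0)),
}

BACKGROUND_HU = 20.0  # soft tissue surrogate outside the lungs

_CLASS_ORDER = (LABEL_EMPH, LABEL_FSAD, LABEL_NORMAL, LABEL_UNCAT)


@dataclass
class PhantomConfig:
    """Parameters of a paired-breath phantom.

    ``class_fractions`` is either one (emph, fSAD, normal, uncat) tuple
    applied to every lobe, or a mapping ``{lobe label 1-5: tuple}``.
    Fractions must be non-negative and sum to 1 per lobe (tol 1e-9).
    ``warp_amplitude`` is the maximum in-lung displacement magnitude in
    voxels; ``warp_smoothness`` the Gaussian correlation scale in voxels.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_fractions: tuple[float, float, float, float] | dict[int, tuple] = (
        0.05, 0.15, 0.78, 0.02)
    noise_sd: float = 0.0
    warp_amplitude: float = 0.0
    warp_smoothness: float = 8.0
    texture_scale: float = 2.0
    cluster_scale: float = 4.0
    seed: int = 0

    def fractions_by_lobe(self) -> dict[int, np.ndarray]:
        if isinstance(self.class_fractions, dict):
            table = {int(k): np.asarray(v, dtype=float) for k, v in self.class_fractions.items()}
            if set(table) != {1, 2, 3, 4, 5}:
                raise ValueError("per-lobe fractions must cover lobes 1-5")
        else:
            f = np.asarray(self.class_fractions, dtype=float)
            table = {lobe: f for lobe in range(1, 6)}
        for lobe, f in table.items():
            if f.shape != (4,) or (f < 0).any():
                raise ValueError(f"lobe {lobe}: need 4 non-negative fractions")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"lobe {lobe}: class fractions sum to {f.sum()!r}, not 1")
        return table

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError("phantom grid must be 3D with every axis >= 32 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0 or self.warp_amplitude < 0 or self.warp_smoothness <= 0:
            raise ValueError("noise_sd/warp_amplitude must be >= 0, warp_smoothness > 0")
        self.fractions_by_lobe()  # validates


@dataclass
class PhantomResult:
    """A generated phantom with its full ground truth."""

    study: PairedStudy
    truth: PRMLabelMap  # per-voxel assigned PRM class
    exp_aligned: np.ndarray  # expiratory HU before warping (on the insp grid)
    applied_warp: DeformationField  # field the generator pulled exp through
    true_alignment: DeformationField  # its inverse: what registration should find


# normalized (center, semi-axes) per lobe, axes = (i, j, k); j separates the lungs
_LOBE_ELLIPSOIDS: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    1: ((0.22, 0.30, 0.50), (0.13, 0.17, 0.24)),  # right upper
    2: ((0.50, 0.30, 0.50), (0.12, 0.17, 0.24)),  # right middle
    3: ((0.78, 0.30, 0.50), (0.13, 0.17, 0.24)),  # right lower
    4: ((0.30, 0.70, 0.50), (0.16, 0.17, 0.24)),  # left upper
    5: ((0.70, 0.70, 0.50), (0.16, 0.17, 0.24)),  # left lower
}


def make_lobe_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Five disjoint ellipsoidal lobes (labels 1-5) on the given grid."""
    coords = [np.arange(n, dtype=float) / (n - 1) for n in shape]
    ii, jj, kk = np.meshgrid(*coords, indexing="ij")
    lobes = np.zeros(shape, dtype=np.int8)
    for label, (center, semi) in _LOBE_ELLIPSOIDS.items():
        r2 = (
            ((ii - center[0]) / semi[0]) ** 2
            + ((jj - center[1]) / semi[1]) ** 2
            + ((kk - center[2]) / semi[2]) ** 2
        )
        lobes[r2 <= 1.0] = label
    return lobes


def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer class counts summing to n, closest to fractions * n."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _smooth_uniform_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially smooth field with ~uniform(0,1) voxel marginals."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = g.std()
    if sd == 0:
        return np.full(shape, 0.5)
    return ndtr(g / sd)


def _random_displacement(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    lung_mask: np.ndarray,
    amplitude: float,
    smoothness: float,
) -> DeformationField:
    """Smooth random field, zero at/outside the mask boundary, max |d| = amplitude."""
    if amplitude == 0:
        return DeformationField.zero(shape)
    comps = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
         for _ in range(3)],
        axis=-1,
    )
    # taper to zero over ~3 voxels inside the lung boundary
    edt = ndimage.distance_transform_edt(lung_mask)
    taper = np.clip(edt / 3.0, 0.0, 1.0)
    comps *= taper[..., None]
    mag = np.linalg.norm(comps, axis=-1).max()
    if mag > 0:
        comps *= amplitude / mag
    return DeformationField(comps)


def generate_phantom_pair(config: PhantomConfig) -> PhantomResult:
    """Generate one paired-breath phantom with ground truth.

    See the module docstring for the construction.  Identical configs (same
    seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    lobes = make_lobe_mask(shape)
    lung = lobes > 0

    # assign classes per lobe at exact (largest-remainder) counts; a smooth
    # random field orders voxels so same-class voxels form coherent patches
    # (cluster_scale=0 degrades to voxel-wise salt-and-pepper assignment)
    labels = np.zeros(shape, dtype=np.int8)
    flat = labels.reshape(-1)
    lobes_flat = lobes.reshape(-1)
    if config.cluster_scale > 0:
        cluster = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=config.cluster_scale
        ).reshape(-1)
    else:
        cluster = None
    for lobe, fracs in sorted(config.fractions_by_lobe().items()):
        idx = np.flatnonzero(lobes_flat == lobe)
        counts = _largest_remainder_counts(fracs, idx.size)
        assigned = np.repeat(np.array(_CLASS_ORDER, dtype=np.int8), counts)
        if cluster is None:
            rng.shuffle(assigned)
            flat[idx] = assigned
        else:
            flat[idx[np.argsort(cluster[idx], kind="stable")]] = assigned

    # one smooth quantile field drives both phases (correlated texture)
    u = _smooth_uniform_field(rng, shape, sigma=config.texture_scale)
    insp = np.full(shape, BACKGROUND_HU)
    exp_aligned = np.full(shape, BACKGROUND_HU)
    for cls in _CLASS_ORDER:
        (ilo, ihi), (elo, ehi) = HU_INTERVALS[cls]
        sel = labels == cls
        insp[sel] = ilo + u[sel] * (ihi - ilo)
        exp_aligned[sel] = elo + u[sel] * (ehi - elo)

    warp = _random_displacement(rng, shape, lung, config.warp_amplitude, config.warp_smoothness)
    exp_observed, _ = apply_displacement(exp_aligned, warp, fill=BACKGROUND_HU)
    exp_observed = np.nan_to_num(exp_observed, nan=BACKGROUND_HU)
    exp_mask_f, _ = apply_displacement(lung.astype(float), warp, fill=0.0)
    exp_lung_mask = np.nan_to_num(exp_mask_f, nan=0.0) > 0.5
    true_alignment = (
        invert_displacement(warp) if config.warp_amplitude > 0 else DeformationField.zero(shape)
    )

    if config.noise_sd > 0:
        insp = insp + rng.normal(0.0, config.noise_sd, size=shape)
        exp_observed = exp_observed + rng.normal(0.0, config.noise_sd, size=shape)

    study = PairedStudy(
        insp=insp,
        exp=exp_observed,
        lung_mask=lung,
        lobe_mask=lobes,
        spacing=tuple(config.spacing),
        exp_lung_mask=exp_lung_mask,
    )
    truth = PRMLabelMap(labels=labels, spacing=tuple(config.spacing))
    return PhantomResult(
        study=study,
        truth=truth,
        exp_aligned=exp_aligned,
        applied_warp=warp,
        true_alignment=true_alignment,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: fixed column order of a generated cohort CSV
COHORT_COLUMNS: list[str] = feature_names() + [
    "age", "sex", "height", "weight", "fev1_fvc", "fev1_pct", "group",
]

_LOBE_REGION = {1: "right_upper", 2: "right_middle", 3: "right_lower",
                4: "left_upper", 5: "left_lower"}
_BASE_LOBE_SHARES = np.array([0.20, 0.12, 0.25, 0.22, 0.21])


@dataclass
class CohortConfig:
    """Generative model of a screening cohort.

    Spirometry is linear in the whole-lung PRM percentages (fraction units
    per percentage point)::

        fev1_fvc = fvc_intercept + fvc_fsad_slope * fSAD% + fvc_emph_slope * Emph% + eps
        fev1_pct = pct_intercept + pct_fsad_slope * fSAD% + pct_emph_slope * Emph% + eps

    Per-subject disease burden (whole-lung fSAD%, Emph%, Uncat%) is gamma
    distributed; per-lobe burden is the subject level jittered lognormally
    (``lobe_variation`` is the log-sd), and all 72 regional features are
    derived from per-lobe class *volumes*, so sums and percentages are
    self-consistent by construction.  Group labels are computed from the
    *noiseless* spirometry values, making the label a deterministic function
    of the features.  The default coefficients put roughly 60% of subjects
    in the normal group, 30% in the high-risk band and 10% in COPD.
    """

    n_subjects: int = 500
    # spirometry model
    fvc_intercept: float = 0.88
    fvc_fsad_slope: float = -0.006
    fvc_emph_slope: float = -0.010
    pct_intercept: float = 1.13
    pct_fsad_slope: float = -0.012
    pct_emph_slope: float = -0.015
    fvc_noise_sd: float = 0.04
    pct_noise_sd: float = 0.08
    # disease-burden marginals (percent units)
    fsad_shape: float = 2.0
    fsad_scale: float = 6.0
    emph_shape: float = 1.2
    emph_scale: float = 2.0
    uncat_shape: float = 1.5
    uncat_scale: float = 1.0
    lobe_variation: float = 0.25
    # anatomy and demographics
    total_lv_mean: float = 4400.0
    total_lv_sd: float = 900.0
    age_mean: float = 68.0
    age_sd: float = 4.0
    p_male: float = 0.47
    height_mean: float = 164.0
    height_sd: float = 8.0
    weight_mean: float = 65.0
    weight_sd: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.fvc_noise_sd < 0 or self.pct_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must lie in [0, 1]")


def _region_features(lobe_lv: np.ndarray, lobe_class_pct: np.ndarray) -> dict[str, np.ndarray]:
    """Aggregate per-lobe volumes into the 72 named features (vectorized over subjects).

    ``lobe_lv``: (n, 5) lobe volumes in mL; ``lobe_class_pct``: (n, 5, 4)
    class percentages per lobe in the order emph, fsad, normal, uncat.
    """
    class_vol = lobe_lv[:, :, None] * lobe_class_pct / 100.0  # (n, 5, 4)
    out: dict[str, np.ndarray] = {}
    for region, lobe_labels in REGIONS.items():
        sel = [l - 1 for l in lobe_labels]
        lv = lobe_lv[:, sel].sum(axis=1)
        vols = class_vol[:, sel, :].sum(axis=1)  # (n, 4)
        out[f"prm_{region}_lv_ml"] = lv
        for ci, cls in enumerate(sorted(CLASS_NAMES)):
            name = CLASS_NAMES[cls]
            out[f"prm_{region}_{name}_ml"] = vols[:, ci]
            out[f"prm_{region}_{name}_pct"] = 100.0 * vols[:, ci] / lv
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns a DataFrame with the 72 PRM features, the four clinical
    features, measured (noisy) ``fev1_fvc`` and ``fev1_pct`` as fractions,
    and the rule-based ``group`` label, in :data:`COHORT_COLUMNS` order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # subject-level disease burden, percent of lung volume
    fsad = rng.gamma(config.fsad_shape, config.fsad_scale, n) if config.fsad_scale > 0 else np.zeros(n)
    emph = rng.gamma(config.emph_shape, config.emph_scale, n) if config.emph_scale > 0 else np.zeros(n)
    uncat = rng.gamma(config.uncat_shape, config.uncat_scale, n) if config.uncat_scale > 0 else np.zeros(n)

    # per-lobe jitter around the subject level, kept self-consistent by
    # deriving every regional feature from per-lobe class volumes
    sig = config.lobe_variation
    jitter = (
        rng.lognormal(-0.5 * sig**2, sig, size=(n, 5, 3)) if sig > 0 else np.ones((n, 5, 3))
    )
    lobe_burden = np.stack([emph, fsad, uncat], axis=-1)[:, None, :] * jitter  # (n,5,3)
    total = lobe_burden.sum(axis=-1, keepdims=True)
    scale = np.where(total > 95.0, 95.0 / np.maximum(total, 1e-12), 1.0)
    lobe_burden = lobe_burden * scale
    lobe_pct = np.concatenate(
        [lobe_burden[:, :, :1],                       # emph
         lobe_burden[:, :, 1:2],                      # fsad
         100.0 - lobe_burden.sum(axis=-1, keepdims=True),  # normal
         lobe_burden[:, :, 2:3]],                     # uncat
        axis=-1,
    )

    total_lv = np.clip(rng.normal(config.total_lv_mean, config.total_lv_sd, n), 2000.0, 8500.0)
    shares = rng.dirichlet(_BASE_LOBE_SHARES * 60.0, size=n)
    lobe_lv = total_lv[:, None] * shares

    features = _region_features(lobe_lv, lobe_pct)

    # spirometry from the emitted whole-lung percentages
    f_whole = features["prm_whole_lung_fsad_pct"]
    e_whole = features["prm_whole_lung_emph_pct"]
    fvc_clean = config.fvc_intercept + config.fvc_fsad_slope * f_whole + config.fvc_emph_slope * e_whole
    pct_clean = config.pct_intercept + config.pct_fsad_slope * f_whole + config.pct_emph_slope * e_whole
    fvc_clean = np.clip(fvc_clean, 0.01, 1.2)
    pct_clean = np.clip(pct_clean, 0.01, 1.6)
    fvc = fvc_clean + (rng.normal(0.0, config.fvc_noise_sd, n) if config.fvc_noise_sd > 0 else 0.0)
    pct = pct_clean + (rng.normal(0.0, config.pct_noise_sd, n) if config.pct_noise_sd > 0 else 0.0)
    fvc = np.clip(fvc, 0.01, 1.2)
    pct = np.clip(pct, 0.01, 1.6)

    groups = staging.classify_table(fvc_clean, pct_clean)["group"].to_numpy()

    df = pd.DataFrame(features)
    df["age"] = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 40, 90)
    df["sex"] = (rng.random(n) < config.p_male).astype(int)  # male=1, female=0
    df["height"] = np.round(rng.normal(config.height_mean, config.height_sd, n), 1)
    df["weight"] = np.round(rng.normal(config.weight_mean, config.weight_sd, n), 1)
    df["fev1_fvc"] = fvc
    df["fev1_pct"] = pct
    df["group"] = groups
    return df[COHORT_COLUMNS]
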