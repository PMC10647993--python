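"""Deformable registration of the expiratory volume onto the inspiratory grid.

PRM classification compares the two phases voxel by voxel, so the expiratory
scan must first be aligned to the inspiratory one.  The default algorithm is
multi-resolution symmetric-forces demons on offset-corrected intensities:

1. expiratory lung is denser than inspiratory lung, so even perfectly
   aligned voxels differ in HU; the mean HU difference over air-like voxels
   (HU < -400) is subtracted from the expiratory lung before matching.
   The correction deliberately leaves non-lung tissue untouched so the
   high-contrast lung boundary stays consistent between the two images.
   (Global histogram matching is *not* used: the inspiratory-to-expiratory
   intensity relation is class-dependent - air-trapping tissue drops
   expiratory density while normal tissue raises it - so no single monotone
   intensity map exists, and forcing one biases the match.)
2. a demons displacement field is estimated coarse-to-fine over a Gaussian
   image pyramid;
3. the field is converted to voxel units on the inspiratory grid and the
   expiratory volume is resampled through it.

A safety check guarantees the result never degrades the objective: if the
masked mean-squared HU difference after warping exceeds the pre-registration
value, the identity field is returned and the result is flagged
non-converged.  The metric mask is the lung mask itself (an optional
dilation is available but off by default; see RegistrationSettings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import DeformationField, PairedStudy, apply_displacement

__all__ = ["RegistrationSettings", "RegistrationResult", "register_exp_to_insp",
           "apply_precomputed_alignment", "masked_mse"]


@dataclass
class RegistrationSettings:
    """Knobs of the demons registration.

    ``iterations`` gives the demons iterations per pyramid level, coarse to
    fine; ``shrink_factors`` the per-level downsampling; ``smoothing_sigmas``
    the pre-smoothing (voxels) per level.  ``field_smoothing_sigma`` is the
    demons regularizer (voxels).  ``offset_correction`` subtracts the mean
    expiration-inspiration HU difference over voxels below ``air_threshold``
    from the expiratory lung before matching.  ``mask_dilation`` voxels of
    lung-mask dilation are applied before metric evaluation; the default is
    0 because the ring just outside the lung boundary carries resampling
    artifacts of the (correctly) discontinuous field there, which would
    contaminate the objective.
    """

    iterations: tuple[int, ...] = (120, 80, 50)
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    field_smoothing_sigma: float = 2.0
    offset_correction: bool = True
    air_threshold: float = -400.0
    mask_dilation: int = 0
    interpolation_order: int = 1

    def __post_init__(self) -> None:
        if not (len(self.iterations) == len(self.shrink_factors) == len(self.smoothing_sigmas)):
            raise ValueError("iterations, shrink_factors and smoothing_sigmas must align")


@dataclass
class RegistrationResult:
    field: DeformationField
    registered_exp: np.ndarray
    valid: np.ndarray  # voxels whose resample stayed inside the moving volume
    mse_before: float
    mse_after: float
    converged: bool = True


def masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared difference over finite masked voxels."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sel = np.asarray(mask, dtype=bool) & np.isfinite(d)
    if not sel.any():
        return 0.0
    return float(np.mean(d[sel] ** 2))


def _to_sitk(vol: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    # numpy axis 0 becomes the sitk z axis; spacing is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol, dtype=np.float64))
    img.SetSpacing((float(spacing[2]), float(spacing[1]), float(spacing[0])))
    return img


def _field_to_voxels(field_img: sitk.Image, spacing: tuple[float, float, float]) -> np.ndarray:
    arr = sitk.GetArrayFromImage(field_img)  # (z, y, x, [x, y, z components]) in mm
    disp = np.empty(arr.shape[:3] + (3,), dtype=float)
    disp[..., 0] = arr[..., 2] / spacing[0]
    disp[..., 1] = arr[..., 1] / spacing[1]
    disp[..., 2] = arr[..., 0] / spacing[2]
    return disp


def _multiscale_demons(
    fixed: sitk.Image, moving: sitk.Image, settings: RegistrationSettings
) -> sitk.Image:
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(settings.field_smoothing_sigma)

    levels = list(zip(settings.shrink_factors, settings.smoothing_sigmas, settings.iterations))
    displacement: sitk.Image | None = None
    for shrink, sigma, iters in levels:
        f = sitk.SmoothingRecursiveGaussian(fixed, sigma) if sigma > 0 else fixed
        m = sitk.SmoothingRecursiveGaussian(moving, sigma) if sigma > 0 else moving
        if shrink > 1:
            f = sitk.Shrink(f, [shrink] * 3)
            m = sitk.Shrink(m, [shrink] * 3)
        if displacement is None:
            displacement = sitk.Image(f.GetSize(), sitk.sitkVectorFloat64)
            displacement.CopyInformation(f)
        else:
            displacement = sitk.Resample(displacement, f, sitk.Transform(), sitk.sitkLinear)
        demons.SetNumberOfIterations(iters)
        displacement = demons.Execute(f, m, displacement)
    return sitk.Resample(displacement, fixed, sitk.Transform(), sitk.sitkLinear)


def register_exp_to_insp(
    study: PairedStudy, settings: RegistrationSettings | None = None
) -> RegistrationResult:
    """Estimate the expiration-to-inspiration displacement field.

    Returns the field in voxel units on the inspiratory grid together with
    the resampled expiratory volume.  On identical inputs the field is
    numerically zero; if the demons solution would *increase* the masked MSE
    relative to no warp, the identity field is returned instead and
    ``converged`` is False (with a warning).
    """
    settings = settings or RegistrationSettings()
    insp = np.asarray(study.insp, dtype=float)
    exp = np.asarray(study.exp, dtype=float)
    metric_mask = np.asarray(study.lung_mask, dtype=bool)
    if settings.mask_dilation > 0:
        metric_mask = ndimage.binary_dilation(metric_mask, iterations=settings.mask_dilation)

    moving = exp
    if settings.offset_correction:
        fixed_air = insp < settings.air_threshold
        moving_air = exp < settings.air_threshold
        if fixed_air.any() and moving_air.any():
            offset = exp[moving_air].mean() - insp[fixed_air].mean()
            moving = exp.copy()
            moving[moving_air] -= offset

    field_img = _multiscale_demons(
        _to_sitk(insp, study.spacing), _to_sitk(moving, study.spacing), settings
    )
    disp = _field_to_voxels(field_img, study.spacing)
    field = DeformationField(disp, interpolation_order=settings.interpolation_order)

    registered, valid = apply_displacement(exp, field)
    # the convergence guard is evaluated on the matching objective, i.e. on
    # the offset-corrected intensities the demons forces actually saw
    moved_objective, valid_obj = apply_displacement(moving, field)
    mse_before = masked_mse(insp, moving, metric_mask)
    mse_after = masked_mse(insp, moved_objective, metric_mask & valid_obj)
    if mse_after > mse_before:
        warnings.warn(
            "registration increased the masked MSE "
            f"({mse_before:.1f} -> {mse_after:.1f}); returning identity",
            stacklevel=2,
        )
        field = DeformationField.zero(insp.shape)
        registered, valid = exp.copy(), np.ones(insp.shape, dtype=bool)
        mse_after = mse_before
        return RegistrationResult(field, registered, valid, mse_before, mse_after, converged=False)
    return RegistrationResult(field, registered, valid, mse_before, mse_after, converged=True)


def apply_precomputed_alignment(
    study: PairedStudy, field: DeformationField, order: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the study's expiratory volume through an externally supplied field.

    Returns ``(registered, valid)``; out-of-volume samples are NaN and
    flagged invalid, and callers should intersect ``valid`` with the lung
    mask before classification.
    """
    exp = np.asarray(study.exp, dtype=float)
    if field.grid_shape != exp.shape:
        raise ValueError(
            f"field grid {field.grid_shape} does not match expiratory volume {exp.shape}"
        )
    return apply_displacement(exp, field, order=order)
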