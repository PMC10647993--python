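"""Shared containers for paired-breath CT volumes and displacement fields.

Conventions
-----------
* Volumes are 3D numpy arrays indexed ``(i, j, k)`` with 0-based voxel
  indices; world coordinates follow from the per-axis spacing in mm only
  (no oblique affines).
* Displacement fields live on the fixed (inspiratory) grid, in *voxel*
  units, stored as an array of shape ``grid + (3,)``.  Resampling a moving
  volume with a field reads ``moving[x + d(x)]`` (a pull-back).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PairedStudy", "DeformationField", "apply_displacement", "invert_displacement"]


@dataclass
class PairedStudy:
    """A registered-or-not inspiratory/expiratory CT pair with its masks.

    ``lung_mask`` and ``lobe_mask`` are defined on the inspiratory grid;
    ``lobe_mask`` codes the five lobes 1-3 (right upper/middle/lower) and
    4-5 (left upper/lower), 0 elsewhere.
    """

    insp: np.ndarray
    exp: np.ndarray
    lung_mask: np.ndarray
    lobe_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    exp_lung_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(self.insp), np.shape(self.exp), np.shape(self.lung_mask),
                  np.shape(self.lobe_mask)}
        if len(shapes) != 1:
            raise ValueError(f"volumes and masks must share one grid, got {shapes}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths in mm")


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (voxel units) on the inspiratory grid."""

    displacement: np.ndarray  # shape grid + (3,)
    interpolation_order: int = 1

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (ni, nj, nk, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    @classmethod
    def zero(cls, grid_shape: tuple[int, int, int]) -> "DeformationField":
        return cls(np.zeros(tuple(grid_shape) + (3,)))


def _sample_coords(field: DeformationField) -> np.ndarray:
    grid = np.indices(field.grid_shape, dtype=float)
    return grid + np.moveaxis(field.displacement, -1, 0)


def apply_displacement(
    volume: np.ndarray,
    field: DeformationField,
    order: int | None = None,
    fill: float = np.nan,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``volume`` through a displacement field (pull-back).

    Returns ``(resampled, valid)`` where ``valid`` is False wherever the
    sample point fell outside the volume; those voxels hold ``fill`` and
    should be removed from any mask that consumes the result.  A zero field
    returns the input unchanged (no interpolation pass).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != field.grid_shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match field grid {field.grid_shape}"
        )
    if not np.any(field.displacement):
        return volume.copy(), np.ones(volume.shape, dtype=bool)
    order = field.interpolation_order if order is None else order
    coords = _sample_coords(field)
    upper = np.array(volume.shape, dtype=float).reshape(3, 1, 1, 1) - 1.0
    valid = np.all((coords >= 0.0) & (coords <= upper), axis=0)
    out = ndimage.map_coordinates(volume, coords, order=order, mode="nearest")
    out[~valid] = fill
    return out, valid


def invert_displacement(field: DeformationField, iterations: int = 15) -> DeformationField:
    """Fixed-point inverse of a (smooth, moderate) displacement field.

    Solves ``t(x) = -d(x + t(x))`` so that pulling a volume back through
    ``d`` and then through ``t`` returns (approximately) the original.
    Accuracy degrades for fields approaching folding; intended for the
    smooth, small-amplitude fields the phantom generator produces.
    """
    d = field.displacement
    t = -d.copy()
    grid = np.indices(field.grid_shape, dtype=float)
    for _ in range(iterations):
        coords = grid + np.moveaxis(t, -1, 0)
        warped = np.stack(
            [ndimage.map_coordinates(d[..., a], coords, order=1, mode="nearest")
             for a in range(3)],
            axis=-1,
        )
        t = -warped
    return DeformationField(t, interpolation_order=field.interpolation_order)
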