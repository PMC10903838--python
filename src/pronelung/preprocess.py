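"""Preprocessing: resampling to a fixed cubic grid and attenuation scaling.

Both scans are resized to ``cube_side``^3 voxels (default 192) with
the physical extent preserved, so the output spacing per axis is
``extent / cube_side`` and may be anisotropic. CT attenuation is clipped to
a lung-window range and divided by ``attenuation_divisor`` (default 3000) so
registration operates on O(1) intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Grid3D, LabelMap, Volume3D
from .errors import ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    cube_side: int = 192
    attenuation_divisor: float = 3000.0
    clip_hu: tuple = (-1024.0, 600.0)
    volume_interpolation: str = "linear"
    label_interpolation: str = "nearest"

    def __post_init__(self):
        if self.cube_side < 16:
            raise ValidationError("cube_side must be >= 16")
        if self.attenuation_divisor <= 0:
            raise ValidationError("attenuation_divisor must be > 0")
        if self.clip_hu[0] >= self.clip_hu[1]:
            raise ValidationError("clip_hu must be (min, max) with min < max")
        if self.volume_interpolation != "linear" or self.label_interpolation != "nearest":
            raise ValidationError("only linear volume / nearest label interpolation is supported")


def _resample_array(values: np.ndarray, in_shape, cube: int, order: int, cval) -> np.ndarray:
    # output index j maps to input index j * n_in / cube (0-based, origin-anchored)
    matrix = np.diag([n / cube for n in in_shape])
    return ndimage.affine_transform(
        values, matrix, offset=0.0, output_shape=(cube, cube, cube),
        order=order, mode="nearest", prefilter=False,
    )


def resample_to_cube(img, cfg: PreprocessConfig | None = None):
    """Resample a volume or label map to a cubic voxel grid.

    The physical extent per axis is unchanged; only the voxel count becomes
    ``cube_side`` (so spacing changes to extent/cube_side). Volumes use
    linear, label maps nearest interpolation (labels are never invented).
    """
    cfg = cfg or PreprocessConfig()
    grid = img.grid
    cube = cfg.cube_side
    if grid.shape == (cube, cube, cube):
        # self-resampling is the identity
        return img
    new_grid = Grid3D(
        (cube, cube, cube),
        tuple(e / cube for e in grid.extent_mm),
        grid.origin,
    )
    if isinstance(img, LabelMap):
        out = _resample_array(img.labels, grid.shape, cube, order=0, cval=0)
        return LabelMap(new_grid, out.astype(img.labels.dtype))
    out = _resample_array(np.asarray(img.values, dtype=np.float32), grid.shape, cube, order=1, cval=0.0)
    return Volume3D(new_grid, out.astype(np.float32), img.unit_tag)


def scale_attenuation(vol: Volume3D, cfg: PreprocessConfig | None = None) -> Volume3D:
    """Clip HU to ``clip_hu`` then divide by the attenuation divisor."""
    cfg = cfg or PreprocessConfig()
    if vol.unit_tag != "HU":
        raise ValidationError("scale_attenuation expects HU input (double-scaling guard)")
    v = np.clip(np.asarray(vol.values, dtype=np.float64), cfg.clip_hu[0], cfg.clip_hu[1])
    # scaled values stay float64 so that unscaling recovers the clipped
    # float32 input exactly
    return Volume3D(vol.grid, v / cfg.attenuation_divisor, "scaled")


def unscale_attenuation(vol: Volume3D, cfg: PreprocessConfig | None = None) -> Volume3D:
    """Invert :func:`scale_attenuation` (recovers the clipped HU values)."""
    cfg = cfg or PreprocessConfig()
    if vol.unit_tag != "scaled":
        raise ValidationError("unscale_attenuation expects scaled input")
    v = np.asarray(vol.values, dtype=np.float64) * cfg.attenuation_divisor
    return Volume3D(vol.grid, v.astype(np.float32), "HU")
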