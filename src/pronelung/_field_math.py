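"""Numerical helpers shared by the phantom generator and the registration
modules: displacement-field sampling, fixed-point inversion and discrete
Jacobian determinants. Displacements are millimetre 3-vectors stored on the
grid, component order (x, y, z) in the package convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def sample_volume(values: np.ndarray, idx: np.ndarray, order: int = 1, cval=None) -> np.ndarray:
    """Sample ``values`` at fractional voxel indices ``idx`` of shape (3, ...)."""
    mode = "nearest" if cval is None else "constant"
    kwargs = {} if cval is None else {"cval": cval}
    return ndimage.map_coordinates(values, idx, order=order, mode=mode, prefilter=False, **kwargs)


def sample_displacement(vectors: np.ndarray, spacing, pts_idx: np.ndarray) -> np.ndarray:
    """Linearly interpolate a (nx, ny, nz, 3) mm-vector field at voxel indices.

    ``pts_idx`` has shape (..., 3); returns mm vectors of the same shape.
    Outside the grid the field is edge-extended (the phantom fields decay to
    zero well inside the grid, so this only matters for degenerate inputs).
    """
    coords = np.moveaxis(pts_idx, -1, 0)
    out = np.empty(pts_idx.shape, dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            vectors[..., c], coords, order=1, mode="nearest", prefilter=False
        )
    return out


def invert_displacement_at(vectors: np.ndarray, grid, pts_mm: np.ndarray, iters: int = 12) -> np.ndarray:
    """Solve x + u(x) = y for x, per point y in ``pts_mm`` (..., 3).

    Simple fixed-point iteration x <- y - u(x); converges for the smooth,
    non-folding fields used here (||grad u|| < 1).
    """
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    y = np.asarray(pts_mm, dtype=np.float64)
    x = y.copy()
    for _ in range(iters):
        u = sample_displacement(vectors, grid.spacing, (x - origin) / spacing)
        x = y - u
    return x


def jacobian_determinant_array(vectors: np.ndarray, spacing) -> np.ndarray:
    """det of the Jacobian of the mapping x -> x + u(x), central differences.

    Computed with an explicit cofactor expansion instead of a stacked
    (..., 3, 3) matrix so large grids stay cheap.
    """
    g = [np.gradient(np.asarray(vectors[..., c], dtype=np.float64), *spacing) for c in range(3)]
    a00 = 1.0 + g[0][0]
    a01, a02 = g[0][1], g[0][2]
    a10, a12 = g[1][0], g[1][2]
    a11 = 1.0 + g[1][1]
    a20, a21 = g[2][0], g[2][1]
    a22 = 1.0 + g[2][2]
    return (
        a00 * (a11 * a22 - a12 * a21)
        - a01 * (a10 * a22 - a12 * a20)
        + a02 * (a10 * a21 - a11 * a20)
    )


def warp_by_displacement(values: np.ndarray, grid, vectors: np.ndarray, order: int, cval) -> np.ndarray:
    """Resample ``values`` at x + u(x) for every grid voxel x."""
    spacing = np.asarray(grid.spacing)
    idx = np.indices(grid.shape, dtype=np.float64)
    for a in range(3):
        idx[a] += vectors[..., a] / spacing[a]
    return ndimage.map_coordinates(values, idx, order=order, mode="constant", cval=cval, prefilter=False)
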