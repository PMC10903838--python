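"""Dense deformable registration: multi-resolution Gaussian-regularized demons.

Produces the spatial displacement map between the supine scan (fixed) and
the affine-registered prone scan (moving): a per-voxel millimetre 3-vector
field u on the fixed grid such that ``moving(x + u(x)) ~= fixed(x)``. The
algorithm is the classic additive demons loop with dual Gaussian
regularization (fluid-like smoothing of each update, elastic-like smoothing
of the accumulated field), run coarse-to-fine over an image pyramid.
Intensities are expected on a common scale; the pipeline feeds the
1/3000-scaled volumes so image gradients are O(1).

Externally computed fields (e.g. from a learning-based registration tool)
can be imported from 4D NIfTI and used interchangeably downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._field_math import jacobian_determinant_array
from .core_io import Grid3D, LabelMap, Volume3D, _lps_affine
from .errors import FormatError, GridMismatchError, ValidationError


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) on the fixed grid, components (x, y, z)."""

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValidationError(
                f"vector array shape {self.vectors.shape} != grid shape + (3,) "
                f"{self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement field contains non-finite entries")

    def magnitude(self) -> np.ndarray:
        return np.sqrt((np.asarray(self.vectors, dtype=np.float64) ** 2).sum(axis=-1))


@dataclass(frozen=True)
class DemonsConfig:
    levels: int = 3                       # pyramid levels, downsampling x2 per level
    iterations_per_level: tuple = (100, 60, 30)  # coarsest -> finest
    update_sigma_mm: float = 2.0          # fluid-like smoothing of each update
    field_sigma_mm: float = 3.0           # elastic-like smoothing of the field
    max_step_mm: float = 2.0              # per-iteration displacement cap
    convergence_tol: float = 1e-4         # relative MSE change

    def __post_init__(self):
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        if len(self.iterations_per_level) < self.levels:
            raise ValidationError("iterations_per_level must list one entry per level")
        if min(self.update_sigma_mm, self.field_sigma_mm, self.max_step_mm) <= 0:
            raise ValidationError("sigmas and max_step_mm must be positive")


@dataclass
class DemonsResult:
    field: DisplacementField
    mse_history: list = dc_field(default_factory=list)  # one list per level, coarse->fine
    converged: bool = False


def _downsample(values: np.ndarray, times: int) -> np.ndarray:
    out = values
    for _ in range(times):
        out = ndimage.gaussian_filter(out, sigma=1.0, truncate=2.0)
        out = out[::2, ::2, ::2]
    return out


def _warp(moving: np.ndarray, u: np.ndarray, spacing, base_idx) -> np.ndarray:
    coords = [base_idx[a] + u[..., a] / spacing[a] for a in range(3)]
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest", prefilter=False)


def _upsample_field(u: np.ndarray, new_shape) -> np.ndarray:
    factors = [n / o for n, o in zip(new_shape, u.shape[:3])]
    out = np.empty(tuple(new_shape) + (3,), dtype=np.float32)
    for c in range(3):
        out[..., c] = ndimage.zoom(u[..., c], factors, order=1, mode="nearest",
                                   prefilter=False, grid_mode=False)
    return out


def register_deformable(fixed: Volume3D, moving: Volume3D,
                        cfg: DemonsConfig | None = None,
                        mask: LabelMap | None = None) -> DemonsResult:
    """Estimate the displacement field aligning ``moving`` onto ``fixed``.

    Per pyramid level, each iteration computes the demons update

        du = (f - m o phi) * grad(m o phi) / (||grad(m o phi)||^2 + (m o phi - f)^2 / kappa)

    with kappa the squared mean voxel spacing, caps its magnitude at
    ``max_step_mm``, smooths it with ``update_sigma_mm``, adds it to the
    field and smooths the field with ``field_sigma_mm``. Iteration stops at
    the per-level cap or when the relative MSE change falls below
    ``convergence_tol``. The MSE history per level is returned for
    diagnostics (it is non-increasing in practice).
    """
    cfg = cfg or DemonsConfig()
    if not fixed.grid.approx_equal(moving.grid):
        raise GridMismatchError("fixed and moving must share a grid (run the affine stage first)")
    if fixed.unit_tag != moving.unit_tag:
        raise ValidationError("fixed and moving must be on a common intensity scale")
    f_full = np.asarray(fixed.values, dtype=np.float32)
    m_full = np.asarray(moving.values, dtype=np.float32)
    if not (np.all(np.isfinite(f_full)) and np.all(np.isfinite(m_full))):
        raise ValidationError("non-finite intensities")
    mask_full = mask.lung_mask() if mask is not None else None

    spacing_full = np.asarray(fixed.grid.spacing)
    u = None
    history = []
    converged = False
    for level in range(cfg.levels - 1, -1, -1):  # coarse -> fine
        f = _downsample(f_full, level)
        m = _downsample(m_full, level)
        spacing = spacing_full * (2 ** level)
        lvl_mask = None
        if mask_full is not None:
            lvl_mask = mask_full[:: 2 ** level, :: 2 ** level, :: 2 ** level][
                : f.shape[0], : f.shape[1], : f.shape[2]
            ]
        if u is None:
            u = np.zeros(f.shape + (3,), dtype=np.float32)
        else:
            u = _upsample_field(u, f.shape)
        base_idx = np.indices(f.shape, dtype=np.float32)
        kappa = float(np.mean(spacing)) ** 2
        # sigmas are physical (mm) but never below one voxel, so coarse
        # pyramid levels stay regularized
        sig_up = np.maximum(cfg.update_sigma_mm / spacing, 1.0)
        sig_fl = np.maximum(cfg.field_sigma_mm / spacing, 1.0)
        n_iter = cfg.iterations_per_level[cfg.levels - 1 - level]
        mse_trace = []
        prev = None
        u_prev = None
        for _ in range(n_iter):
            warped = _warp(m, u, spacing, base_idx)
            diff = warped - f
            mse = float(np.mean(diff[lvl_mask] ** 2)) if lvl_mask is not None else float(np.mean(diff**2))
            if prev is not None and mse >= prev:
                # the last update did not descend: revert it and stop the level
                u = u_prev
                converged = True
                break
            mse_trace.append(mse)
            if prev is not None and prev - mse <= cfg.convergence_tol * max(prev, 1e-20):
                converged = True
                break
            prev = mse
            u_prev = u.copy()
            grads = np.gradient(warped, *spacing)
            gnorm2 = grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2
            denom = gnorm2 + diff**2 / kappa
            scale = np.where(denom > 1e-12, -diff / np.maximum(denom, 1e-12), 0.0)
            upd = np.empty_like(u)
            for a in range(3):
                upd[..., a] = scale * grads[a]
            step = np.sqrt((upd**2).sum(axis=-1))
            over = step > cfg.max_step_mm
            if over.any():
                shrink = np.ones_like(step)
                shrink[over] = cfg.max_step_mm / step[over]
                upd *= shrink[..., None]
            for a in range(3):
                upd[..., a] = ndimage.gaussian_filter(upd[..., a], sig_up, truncate=2.0)
            u += upd
            for a in range(3):
                u[..., a] = ndimage.gaussian_filter(u[..., a], sig_fl, truncate=2.0)
        history.append(mse_trace)
    return DemonsResult(
        field=DisplacementField(fixed.grid, u.astype(np.float32)),
        mse_history=history,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Field I/O and diagnostics
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def export_field(field: DisplacementField, path) -> None:
    """Write a field as 4D NIfTI (4th axis = x, y, z components, mm) plus a
    JSON sidecar stating units and axis convention."""
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float32), _lps_affine(field.grid))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"units": "mm", "axis_convention": "LPS", "components": ["x", "y", "z"]})
    )


def import_field(path, expected_grid: Grid3D, units: str | None = None) -> DisplacementField:
    """Read a 4D NIfTI displacement field and validate it against a grid.

    Units come from the JSON sidecar when present; otherwise they must be
    given explicitly (``"mm"`` or ``"voxels"``; voxel-unit vectors are
    converted through the grid spacing).
    """
    img = nib.load(str(path))
    shape = tuple(img.shape)
    if len(shape) != 4 or shape[3] != 3:
        raise FormatError(
            f"{path}: expected a 4D field with 3 components, got shape {shape}"
        )
    sidecar = _sidecar_path(path)
    if units is None:
        if not sidecar.exists():
            raise FormatError(
                f"{path}: no units metadata found; pass units explicitly (--units mm|voxels)"
            )
        meta = json.loads(sidecar.read_text())
        units = meta.get("units")
    if units not in ("mm", "voxels"):
        raise FormatError(f"{path}: unsupported units {units!r}")
    vectors = np.asanyarray(img.dataobj).astype(np.float32)
    if shape[:3] != expected_grid.shape:
        raise GridMismatchError(
            f"{path}: field shape {shape[:3]} does not match expected grid {expected_grid.shape}"
        )
    if units == "voxels":
        vectors = vectors * np.asarray(expected_grid.spacing, dtype=np.float32)
    return DisplacementField(expected_grid, vectors)


def jacobian_determinant(field: DisplacementField) -> Volume3D:
    """Local volume-change factor of x -> x + u(x); <= 0 indicates folding."""
    det = jacobian_determinant_array(field.vectors, field.grid.spacing)
    return Volume3D(field.grid, det.astype(np.float32), "dimensionless")
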