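"""Synthetic prone/supine thoracic phantom generator.

The generator produces paired supine and prone CT-like volumes with known
ground truth, emulating the structure the registration analysis assumes:

* two ellipsoidal lungs (~-850 HU) inside a body ellipsoid (~+40 HU),
  partitioned into the five lobes by one oblique fissure plane per lung plus
  the right horizontal fissure;
* optional fibrosis-like regions (~-300 HU) placed dorsal-basal subpleural
  first, mirroring the usual-interstitial-pneumonia distribution;
* a prone pose difference modelled as a modest residual shear-free affine
  (not a 180-degree scanner flip: patient-anatomy coordinates already absorb
  the flip, so only residual centring/rotation/scale remains);
* a smooth dorsal-caudal expansion deformation built from Gaussian
  displacement bumps, normalized so its peak magnitude equals
  ``deformation_amplitude_mm`` and its lower-lobe volume gain matches
  ``lower_lobe_expansion_ml``, then damped by a factor ``(1 - damping)``
  inside fibrotic voxels (fibrosis locally stiffens the lung).

Ground truth (pose, displacement field, labels, fissure planes) travels with
each pair so registration and volumetry can be validated against it. All
randomness uses numpy's PCG64 generator seeded from ``PhantomSpec.seed``;
identical specs produce bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import core_io
from ._field_math import (
    invert_displacement_at,
    jacobian_determinant_array,
    warp_by_displacement,
)
from .core_io import Grid3D, LabelMap, SubjectRecord, Volume3D
from .errors import GridMismatchError, SpecError, ValidationError
from .register_deformable import DisplacementField
from .transforms import AffineTransform

_HU_MIN, _HU_MAX = -1024.0, 3071.0
_AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseParams:
    """Explicit prone-vs-supine pose: translation (mm), intrinsic xyz Euler
    rotation (degrees) and isotropic scale."""

    translation_mm: tuple = (0.0, 0.0, 0.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    scale: float = 1.0


@dataclass(frozen=True)
class PoseRanges:
    """Uniform sampling ranges used when the pose is drawn."""

    max_translation_mm: float = 10.0
    max_rotation_deg: float = 8.0
    scale_range: tuple = (0.97, 1.03)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom pair.

    ``fibrosis_extent`` is the fraction of lung volume given fibrosis-like
    attenuation (dorsal-basal subpleural placement); ``damping`` is the
    fractional amplitude reduction of the deformation inside those voxels.
    ``pose=None`` draws translation/rotation/scale uniformly from
    ``pose_ranges`` using the phantom seed.
    """

    shape: tuple = (96, 96, 96)
    spacing_mm: tuple = (3.0, 3.0, 3.0)
    lung_hu: float = -850.0
    body_hu: float = 40.0
    fibrosis_hu: float = -300.0
    noise_sd_hu: float = 20.0
    fibrosis_extent: float = 0.0
    pose: PoseParams | None = None
    pose_ranges: PoseRanges = dc_field(default_factory=PoseRanges)
    deformation_amplitude_mm: float = 15.0
    damping: float = 0.8
    lower_lobe_expansion_ml: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lung_hu", "body_hu", "fibrosis_hu"):
            v = getattr(self, name)
            if not _HU_MIN <= v <= _HU_MAX:
                raise SpecError(f"{name}={v} outside the HU range [{_HU_MIN}, {_HU_MAX}]")
        if self.noise_sd_hu < 0:
            raise SpecError("noise_sd_hu must be non-negative")
        if not 0.0 <= self.fibrosis_extent <= 1.0:
            raise SpecError("fibrosis_extent must be in [0, 1]")
        if self.fibrosis_extent > 0.95:
            raise SpecError(
                f"fibrosis_extent={self.fibrosis_extent} is infeasible (> 0.95 of the lung)"
            )
        if not 0.0 <= self.damping <= 1.0:
            raise SpecError("damping must be in [0, 1]")
        if self.deformation_amplitude_mm < 0:
            raise SpecError("deformation_amplitude_mm must be non-negative")

    @property
    def grid(self) -> Grid3D:
        return Grid3D(self.shape, self.spacing_mm)


@dataclass(frozen=True)
class FissurePlanes:
    """Geometric fissures as (point_mm, unit_normal) pairs.

    A right-lung voxel is RLL when it lies on the positive side of the
    oblique plane, otherwise RUL above the horizontal plane and RML below
    it; a left-lung voxel is LLL on the positive side of the left oblique
    plane and LUL otherwise.
    """

    right_oblique: tuple  # (point, normal)
    right_horizontal: tuple
    left_oblique: tuple

    def to_dict(self) -> dict:
        return {
            name: {"point_mm": list(map(float, p)), "normal": list(map(float, n))}
            for name, (p, n) in (
                ("right_oblique", self.right_oblique),
                ("right_horizontal", self.right_horizontal),
                ("left_oblique", self.left_oblique),
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FissurePlanes":
        def pair(name):
            e = d[name]
            return (tuple(e["point_mm"]), tuple(e["normal"]))

        return cls(pair("right_oblique"), pair("right_horizontal"), pair("left_oblique"))

    def pushed_through(self, T: AffineTransform) -> "FissurePlanes":
        """Planes seen in the domain of ``T``: the supine-space fissures of a
        scan whose points map to supine space through ``T`` (e.g. the prone
        scan under the pose transform)."""
        Ti = T.inverse()
        L = T.linear

        def move(plane):
            p, n = np.asarray(plane[0]), np.asarray(plane[1])
            n2 = L.T @ n
            n2 = n2 / np.linalg.norm(n2)
            return (tuple(Ti.apply_points(p)), tuple(n2))

        return FissurePlanes(
            move(self.right_oblique), move(self.right_horizontal), move(self.left_oblique)
        )


@dataclass
class PhantomPair:
    """A supine/prone phantom with its ground truth.

    ``true_pose`` maps prone-space physical points to (deformed) supine-space
    points; ``true_field`` is the dense displacement (mm) on the supine grid
    such that supine anatomy at x appears at x + u(x) in the affine-aligned
    prone scan.
    """

    supine_vol: Volume3D
    supine_labels: LabelMap
    prone_vol: Volume3D
    prone_labels: LabelMap
    true_pose: AffineTransform
    true_field: DisplacementField
    spec: PhantomSpec
    fissures: FissurePlanes  # supine-space fissure planes

    @property
    def prone_fissures(self) -> FissurePlanes:
        """Fissure planes in prone-scan space (pose-corrected; the residual
        deformation still bends the true fissure surfaces slightly)."""
        return self.fissures.pushed_through(self.true_pose)


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Anatomy:
    body_center: np.ndarray
    body_semi: np.ndarray
    lung_center: dict  # side -> center (mm)
    lung_semi: dict
    fissures: FissurePlanes


def _build_anatomy(grid: Grid3D) -> _Anatomy:
    E = np.asarray(grid.extent_mm)
    body_c = 0.5 * E
    body_s = np.array([0.42, 0.34, 0.46]) * E
    centers = {
        "right": np.array([0.34, 0.47, 0.52]) * E,
        "left": np.array([0.66, 0.47, 0.52]) * E,
    }
    semis = {
        "right": np.array([0.145, 0.21, 0.32]) * E,
        "left": np.array([0.135, 0.21, 0.32]) * E,
    }
    n_ob = np.array([0.0, 0.55, -0.835])
    n_ob = n_ob / np.linalg.norm(n_ob)
    fissures = FissurePlanes(
        right_oblique=(tuple(centers["right"] + 6.0 * n_ob), tuple(n_ob)),
        right_horizontal=(tuple(centers["right"] + [0.0, 0.0, 0.15 * semis["right"][2]]), (0.0, 0.0, 1.0)),
        left_oblique=(tuple(centers["left"] + 6.0 * n_ob), tuple(n_ob)),
    )
    return _Anatomy(body_c, body_s, centers, semis, fissures)


def _inside_ellipsoid(X, Y, Z, c, s):
    return ((X - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2 + ((Z - c[2]) / s[2]) ** 2 <= 1.0


def _plane_side(X, Y, Z, plane):
    (px, py, pz), (nx, ny, nz) = plane
    return (X - px) * nx + (Y - py) * ny + (Z - pz) * nz


def lobes_from_planes(side_labels: np.ndarray, grid: Grid3D, fissures: FissurePlanes) -> np.ndarray:
    """Split right/left lung labels into the five lobes by the fissure planes."""
    X, Y, Z = np.meshgrid(*grid.axes_mm(), indexing="ij", sparse=True)
    right = np.isin(side_labels, core_io.RIGHT_LABELS)
    left = np.isin(side_labels, core_io.LEFT_LABELS)
    out = np.zeros(side_labels.shape, dtype=np.int16)
    s_ro = _plane_side(X, Y, Z, fissures.right_oblique)
    s_rh = _plane_side(X, Y, Z, fissures.right_horizontal)
    s_lo = _plane_side(X, Y, Z, fissures.left_oblique)
    s_ro, s_rh, s_lo = np.broadcast_to(s_ro, out.shape), np.broadcast_to(s_rh, out.shape), np.broadcast_to(s_lo, out.shape)
    out[right & (s_ro > 0)] = 3
    out[right & (s_ro <= 0) & (s_rh > 0)] = 1
    out[right & (s_ro <= 0) & (s_rh <= 0)] = 2
    out[left & (s_lo > 0)] = 5
    out[left & (s_lo <= 0)] = 4
    return out


def _labels_at(X, Y, Z, anat: _Anatomy) -> np.ndarray:
    shape = np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z))
    out = np.zeros(shape, dtype=np.int16)
    right = _inside_ellipsoid(X, Y, Z, anat.lung_center["right"], anat.lung_semi["right"])
    left = _inside_ellipsoid(X, Y, Z, anat.lung_center["left"], anat.lung_semi["left"])
    s_ro = np.broadcast_to(_plane_side(X, Y, Z, anat.fissures.right_oblique), shape)
    s_rh = np.broadcast_to(_plane_side(X, Y, Z, anat.fissures.right_horizontal), shape)
    s_lo = np.broadcast_to(_plane_side(X, Y, Z, anat.fissures.left_oblique), shape)
    right = np.broadcast_to(right, shape)
    left = np.broadcast_to(left, shape)
    out[right & (s_ro > 0)] = 3
    out[right & (s_ro <= 0) & (s_rh > 0)] = 1
    out[right & (s_ro <= 0) & (s_rh <= 0)] = 2
    out[left & (s_lo > 0)] = 5
    out[left & (s_lo <= 0)] = 4
    return out


def _hu_at(X, Y, Z, anat: _Anatomy, spec: PhantomSpec, fib_mask, grid: Grid3D) -> np.ndarray:
    shape = np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z))
    hu = np.full(shape, _AIR_HU, dtype=np.float64)
    body = np.broadcast_to(_inside_ellipsoid(X, Y, Z, anat.body_center, anat.body_semi), shape)
    hu[body] = spec.body_hu
    lung = np.broadcast_to(
        _inside_ellipsoid(X, Y, Z, anat.lung_center["right"], anat.lung_semi["right"])
        | _inside_ellipsoid(X, Y, Z, anat.lung_center["left"], anat.lung_semi["left"]),
        shape,
    )
    hu[lung] = spec.lung_hu
    if fib_mask is not None and fib_mask.any():
        # nearest-voxel lookup of the supine-grid fibrosis region
        idx = []
        for a, C in enumerate((X, Y, Z)):
            i = np.round((np.broadcast_to(C, shape) - grid.origin[a]) / grid.spacing[a]).astype(np.intp)
            idx.append(np.clip(i, 0, grid.shape[a] - 1))
        fib = fib_mask[tuple(idx)] & lung
        hu[fib] = spec.fibrosis_hu
    return hu


def _fibrosis_mask(labels: np.ndarray, grid: Grid3D, extent: float) -> np.ndarray:
    """Select the dorsal-basal subpleural fraction of lung voxels."""
    lung = labels > 0
    out = np.zeros_like(lung)
    if extent <= 0 or not lung.any():
        return out
    depth = ndimage.distance_transform_edt(lung, sampling=grid.spacing)
    X, Y, Z = np.meshgrid(*grid.axes_mm(), indexing="ij", sparse=True)
    yv = np.broadcast_to(Y, lung.shape)[lung]
    zv = np.broadcast_to(Z, lung.shape)[lung]
    dv = depth[lung]
    ynorm = (yv - yv.min()) / max(np.ptp(yv), 1e-9)
    znorm = (zv - zv.min()) / max(np.ptp(zv), 1e-9)
    dnorm = dv / max(dv.max(), 1e-9)
    score = 1.1 * ynorm + 1.0 * (1.0 - znorm) + 1.6 * (1.0 - dnorm)
    k = int(round(extent * score.size))
    order = np.argsort(-score, kind="stable")[:k]
    flat_idx = np.flatnonzero(lung)[order]
    out.ravel()[flat_idx] = True
    return out


# ---------------------------------------------------------------------------
# Ground-truth displacement field
# ---------------------------------------------------------------------------

def _gaussian_bump(X, Y, Z, center, sigma):
    return np.exp(
        -0.5
        * (
            ((X - center[0]) / sigma[0]) ** 2
            + ((Y - center[1]) / sigma[1]) ** 2
            + ((Z - center[2]) / sigma[2]) ** 2
        )
    )


def _movement_bumps(anat: _Anatomy, grid: Grid3D) -> np.ndarray:
    """Dorsal-caudal displacement bumps, peak magnitude normalized to 1."""
    X, Y, Z = np.meshgrid(*grid.axes_mm(), indexing="ij", sparse=True)
    U = np.zeros(grid.shape + (3,), dtype=np.float64)
    for side, xsign in (("right", -1.0), ("left", 1.0)):
        c = anat.lung_center[side]
        s = anat.lung_semi[side]
        bumps = [
            (c + np.array([0.0, 0.45 * s[1], -0.55 * s[2]]),
             np.array([0.7 * s[0], 0.5 * s[1], 0.45 * s[2]]),
             np.array([0.28 * xsign, 0.68, -0.68]), 1.0),
            (c + np.array([0.0, 0.5 * s[1], -0.1 * s[2]]),
             np.array([0.7 * s[0], 0.5 * s[1], 0.5 * s[2]]),
             np.array([0.2 * xsign, 0.75, -0.63]), 0.55),
        ]
        for center, sigma, direction, w in bumps:
            d = direction / np.linalg.norm(direction)
            g = _gaussian_bump(X, Y, Z, center, sigma)
            U += w * g[..., None] * d
    peak = np.sqrt((U ** 2).sum(axis=-1)).max()
    if peak > 0:
        U /= peak
    return U


def _expansion_field(labels: np.ndarray, grid: Grid3D) -> np.ndarray:
    """Unit radial-expansion field centred on each lower lobe."""
    X, Y, Z = np.meshgrid(*grid.axes_mm(), indexing="ij", sparse=True)
    U = np.zeros(grid.shape + (3,), dtype=np.float64)
    min_sigma = 2.0 * max(grid.spacing)
    for lab in (3, 5):
        mask = labels == lab
        if not mask.any():
            continue
        pts = np.argwhere(mask) * np.asarray(grid.spacing) + np.asarray(grid.origin)
        c = pts.mean(axis=0)
        sigma = np.maximum(1.4 * pts.std(axis=0), min_sigma)
        g = _gaussian_bump(X, Y, Z, c, sigma)
        for a, C in enumerate((X, Y, Z)):
            U[..., a] += g * (np.broadcast_to(C, grid.shape) - c[a]) / 100.0
    return U


def _lower_lobe_gain_ml(U: np.ndarray, labels: np.ndarray, grid: Grid3D) -> float:
    det = jacobian_determinant_array(U, grid.spacing)
    lower = np.isin(labels, (3, 5))
    return float((det[lower] - 1.0).sum() * grid.voxel_volume_mm3 / 1000.0)


def _solve_peak_scale(a, b, c, amplitude: float) -> float:
    """Find s >= 0 with max_vox(s^2 a + 2 s b + c) == amplitude^2 (bisection)."""
    target = amplitude ** 2
    if c.max() >= target:
        return 0.0
    hi = amplitude + float(np.sqrt(c.max()))
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if (mid * mid * a + 2.0 * mid * b + c).max() > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _build_true_field(spec: PhantomSpec, anat: _Anatomy, labels: np.ndarray, grid: Grid3D) -> np.ndarray:
    """Undamped ground-truth field: peak == amplitude, lower-lobe gain == target."""
    A = spec.deformation_amplitude_mm
    if A <= 0:
        return np.zeros(grid.shape + (3,), dtype=np.float64)
    Um = _movement_bumps(anat, grid)
    Ue = _expansion_field(labels, grid)
    target = spec.lower_lobe_expansion_ml
    g_unit = _lower_lobe_gain_ml(Ue, labels, grid)
    a = (Um ** 2).sum(axis=-1)

    def field_and_gain(s_e):
        ue = s_e * Ue
        b = (Um * ue).sum(axis=-1)
        c = (ue ** 2).sum(axis=-1)
        if c.max() >= A ** 2:  # expansion alone exceeds the peak budget
            s_e = float(np.sign(s_e)) * 0.9 * A / float(np.sqrt((Ue ** 2).sum(axis=-1).max()))
            ue = s_e * Ue
            b = (Um * ue).sum(axis=-1)
            c = (ue ** 2).sum(axis=-1)
        s_m = _solve_peak_scale(a, b, c, A)
        U = s_m * Um + ue
        return U, _lower_lobe_gain_ml(U, labels, grid), s_e

    # Secant solve on the expansion scale: the movement bumps already carry
    # a gain offset, so gain(s_e) is affine to good accuracy.
    U, g0, s0 = field_and_gain(0.0)
    if abs(g_unit) < 1e-9:
        return U
    s1 = (target - g0) / g_unit
    best = (U, abs(g0 - target))
    g_prev, s_prev = g0, s0
    for _ in range(6):
        U, g1, s1 = field_and_gain(s1)
        if abs(g1 - target) < best[1]:
            best = (U, abs(g1 - target))
        if abs(g1 - target) <= 0.01 * max(abs(target), 1e-6):
            break
        if abs(g1 - g_prev) < 1e-9:
            break
        s_next = s1 + (target - g1) * (s1 - s_prev) / (g1 - g_prev)
        s_prev, g_prev = s1, g1
        s1 = s_next
    return best[0]


def _damping_map(spec: PhantomSpec, fib_mask: np.ndarray, grid: Grid3D) -> np.ndarray:
    """1 - damping at fibrotic voxels, ramping linearly back to 1 outside.

    The ramp keeps the damped field diffeomorphic; a hard step at the
    fibrosis boundary would fold the deformation.
    """
    if spec.damping <= 0 or not fib_mask.any():
        return np.ones(grid.shape, dtype=np.float64)
    dist = ndimage.distance_transform_edt(~fib_mask, sampling=grid.spacing)
    ramp_mm = max(12.0, 2.0 * spec.damping * spec.deformation_amplitude_mm)
    m = np.clip(1.0 - dist / ramp_mm, 0.0, 1.0)
    return 1.0 - spec.damping * m


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_pose(spec: PhantomSpec, rng: np.random.Generator) -> PoseParams:
    r = spec.pose_ranges
    t = rng.uniform(-r.max_translation_mm, r.max_translation_mm, size=3)
    rot = rng.uniform(-r.max_rotation_deg, r.max_rotation_deg, size=3)
    s = rng.uniform(r.scale_range[0], r.scale_range[1])
    return PoseParams(tuple(t), tuple(rot), float(s))


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one supine/prone phantom pair with ground truth.

    The prone scan is the supine anatomy pushed forward by the (damped)
    displacement field and then observed through the pose transform, with
    independent Gaussian noise added to each scan after warping so that
    registration cannot exploit shared noise.
    """
    spec.validate()
    grid = spec.grid
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    anat = _build_anatomy(grid)

    pose = spec.pose if spec.pose is not None else _draw_pose(spec, rng)
    true_pose = AffineTransform.from_params(
        pose.translation_mm, pose.rotation_deg, pose.scale, grid.center_mm
    )

    X, Y, Z = np.meshgrid(*grid.axes_mm(), indexing="ij", sparse=True)
    supine_labels = _labels_at(X, Y, Z, anat)
    fib_mask = _fibrosis_mask(supine_labels, grid, spec.fibrosis_extent)
    supine_hu = _hu_at(X, Y, Z, anat, spec, fib_mask, grid)

    U = _build_true_field(spec, anat, supine_labels, grid)
    damp = _damping_map(spec, fib_mask, grid)
    Ud = (U * damp[..., None]).astype(np.float64)

    lung = supine_labels > 0
    if Ud.any():
        det = jacobian_determinant_array(Ud, grid.spacing)
        if det[lung].min() <= 0.0:
            raise SpecError(
                "deformation folds (non-positive Jacobian inside the lung); "
                "reduce deformation_amplitude_mm or lower_lobe_expansion_ml"
            )

    # Prone sampling points: invert x + u(x) = pose(q) for each prone voxel q.
    coords = np.stack(np.meshgrid(*grid.axes_mm(), indexing="ij"), axis=-1)
    pts = true_pose.apply_points(coords)
    if Ud.any():
        src = invert_displacement_at(Ud, grid, pts)
    else:
        src = pts
    prone_hu = _hu_at(src[..., 0], src[..., 1], src[..., 2], anat, spec, fib_mask, grid)
    prone_labels = _labels_at(src[..., 0], src[..., 1], src[..., 2], anat)

    if spec.noise_sd_hu > 0:
        supine_hu = supine_hu + rng.normal(0.0, spec.noise_sd_hu, size=grid.shape)
        prone_hu = prone_hu + rng.normal(0.0, spec.noise_sd_hu, size=grid.shape)

    return PhantomPair(
        supine_vol=Volume3D(grid, supine_hu.astype(np.float32), "HU"),
        supine_labels=LabelMap(grid, supine_labels),
        prone_vol=Volume3D(grid, prone_hu.astype(np.float32), "HU"),
        prone_labels=LabelMap(grid, prone_labels),
        true_pose=true_pose,
        true_field=DisplacementField(grid, Ud.astype(np.float32)),
        spec=spec,
        fissures=anat.fissures,
    )


# ---------------------------------------------------------------------------
# Warping primitive
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"linear": 1, "nearest": 0}


def apply_deformation(img, field: DisplacementField, interpolation: str = "linear", fill=None):
    """Warp a volume or label map by a displacement field on the same grid.

    Output value at voxel p is the input sampled at ``pos(p) + field(p)``;
    out-of-volume samples take ``fill`` (default -1024 HU for attenuation,
    0 for labels). Label maps always use nearest interpolation.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValidationError(f"interpolation must be one of {tuple(_INTERP_ORDER)}")
    if not img.grid.approx_equal(field.grid):
        raise GridMismatchError("image and displacement field must share a grid")
    if isinstance(img, LabelMap):
        warped = warp_by_displacement(img.labels, img.grid, field.vectors, order=0,
                                      cval=0 if fill is None else fill)
        return LabelMap(img.grid, warped.astype(img.labels.dtype))
    if isinstance(img, Volume3D):
        if fill is None:
            fill = {"HU": -1024.0, "scaled": -1024.0 / 3000.0, "dimensionless": 0.0}[img.unit_tag]
        order = _INTERP_ORDER[interpolation]
        warped = warp_by_displacement(np.asarray(img.values, dtype=np.float32), img.grid,
                                      field.vectors, order=order, cval=fill)
        return Volume3D(img.grid, warped.astype(np.float32), img.unit_tag)
    raise ValidationError(f"cannot warp object of type {type(img).__name__}")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortModel:
    """Covariate model linking fibrosis, deformation amplitude and FVC.

    Fibrosis extent is drawn from a discrete distribution over {0,...,70}%
    (weights follow the visual-assessment distribution of a typical ILD
    cohort); amplitude decreases with fibrosis and FVC increases with
    amplitude, so more fibrotic subjects move less and blow less.
    """

    extent_values: tuple = (0, 10, 20, 30, 40, 50, 60, 70)
    extent_weights: tuple = (12, 7, 20, 21, 12, 19, 13, 3)
    amp_intercept_mm: float = 20.0
    amp_slope_mm_per_pct: float = 0.15
    amp_sd_mm: float = 2.0
    amp_floor_mm: float = 2.0
    fvc_intercept_l: float = 1.5
    fvc_slope_l_per_mm: float = 0.08
    fvc_sd_l: float = 0.3
    expansion_ml_per_mm: float = 80.0 / 15.0


def draw_cohort_plan(n: int, model: CohortModel | None = None, seed: int = 0) -> list:
    """Draw per-subject covariates (fibrosis extent, amplitude, FVC, seed).

    Returns one dict per subject; :func:`generate_cohort` realizes each as a
    phantom pair. Exposed separately so the covariate model can be studied
    without paying for image generation.
    """
    if n < 2:
        raise ValidationError("a cohort needs n >= 2 subjects")
    model = model or CohortModel()
    rng = np.random.Generator(np.random.PCG64(seed))
    weights = np.asarray(model.extent_weights, dtype=np.float64)
    weights = weights / weights.sum()
    plan = []
    for i in range(n):
        extent = float(rng.choice(model.extent_values, p=weights))
        amp = max(
            model.amp_floor_mm,
            model.amp_intercept_mm - model.amp_slope_mm_per_pct * extent + rng.normal(0.0, model.amp_sd_mm),
        )
        fvc = max(0.3, model.fvc_intercept_l + model.fvc_slope_l_per_mm * amp + rng.normal(0.0, model.fvc_sd_l))
        child_seed = int(rng.integers(0, 2**31 - 1))
        if extent == 0:
            pattern = "normal"
        elif extent >= 40:
            pattern = "UIP_or_probable"
        else:
            pattern = "indeterminate_or_alternative"
        plan.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "fibrosis_extent_pct": extent,
                "deformation_amplitude_mm": amp,
                "lower_lobe_expansion_ml": model.expansion_ml_per_mm * amp,
                "fvc_l": round(fvc, 3),
                "pattern_group": pattern,
                "seed": child_seed,
            }
        )
    return plan


def generate_cohort(n: int, model: CohortModel | None = None, seed: int = 0,
                    base_spec: PhantomSpec | None = None) -> list:
    """Generate ``n`` phantom subjects as (PhantomPair, SubjectRecord) tuples."""
    base = base_spec or PhantomSpec()
    out = []
    for item in draw_cohort_plan(n, model=model, seed=seed):
        spec_i = dataclasses.replace(
            base,
            fibrosis_extent=item["fibrosis_extent_pct"] / 100.0,
            deformation_amplitude_mm=item["deformation_amplitude_mm"],
            lower_lobe_expansion_ml=item["lower_lobe_expansion_ml"],
            seed=item["seed"],
            pose=None,
        )
        pair = generate_phantom_pair(spec_i)
        record = SubjectRecord(
            subject_id=item["subject_id"],
            fibrosis_extent=item["fibrosis_extent_pct"],
            pattern_group=item["pattern_group"],
            fvc_l=item["fvc_l"],
        )
        out.append((pair, record))
    return out
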