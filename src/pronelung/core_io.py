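"""Domain types and on-disk I/O.

This module is the coordinate-convention authority for the whole package.
All in-memory arrays follow a fixed patient-anatomy convention:

* array axis 0 (+x): patient right -> left
* array axis 1 (+y): patient anterior -> posterior
* array axis 2 (+z): patient inferior -> superior

i.e. the voxel axes are aligned with the LPS anatomical directions, and the
physical position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
(0-based indices, millimetres). NIfTI files written by any tool whose affine
encodes an axis-aligned acquisition are permuted/flipped into this convention
on read; oblique acquisitions are rejected rather than resliced.

All physical quantities are millimetres and millilitres internally;
centimetres appear only at reporting boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, OrientationError, ValidationError

AXIS_CONVENTION = "LPS"
_TARGET_AXCODES = ("L", "P", "S")

#: Lobe label legend shared by every LabelMap in the package.
LOBE_LEGEND = {
    0: "background",
    1: "RUL",
    2: "RML",
    3: "RLL",
    4: "LUL",
    5: "LLL",
}
RIGHT_LABELS = (1, 2, 3)
LEFT_LABELS = (4, 5)
LUNG_LABELS = RIGHT_LABELS + LEFT_LABELS

PATTERN_GROUPS = ("normal", "UIP_or_probable", "indeterminate_or_alternative")


def _triple(value, name: str, dtype=float) -> tuple:
    try:
        t = tuple(dtype(v) for v in value)
    except TypeError:
        raise ValidationError(f"{name} must be a length-3 sequence, got {value!r}")
    if len(t) != 3:
        raise ValidationError(f"{name} must have length 3, got {value!r}")
    return t


@dataclass(frozen=True)
class Grid3D:
    """Regular 3D sampling grid in patient-anatomy (LPS) coordinates.

    Parameters
    ----------
    shape
        Voxels per axis; every entry must be >= 2.
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    axis_convention: str = field(default=AXIS_CONVENTION, init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "shape", _triple(self.shape, "shape", int))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        if any(n < 2 for n in self.shape):
            raise ValidationError(f"all shape entries must be >= 2, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def extent_mm(self) -> tuple:
        """Physical extent covered per axis: ``shape * spacing`` (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center_mm(self) -> tuple:
        return tuple(o + (n - 1) * s / 2.0 for o, n, s in zip(self.origin, self.shape, self.spacing))

    def axes_mm(self) -> tuple:
        """1D physical coordinate arrays per axis (broadcast-friendly)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a], dtype=np.float64)
            for a in range(3)
        )

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to fractional voxel indices."""
        pts = np.asarray(pts, dtype=np.float64)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def approx_equal(self, other: "Grid3D", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class Volume3D:
    """Scalar 3D image on a :class:`Grid3D`.

    ``unit_tag`` is ``"HU"`` for CT attenuation, ``"scaled"`` after division
    by the configured attenuation divisor, or ``"dimensionless"`` for derived
    maps such as Jacobian determinants.
    """

    grid: Grid3D
    values: np.ndarray
    unit_tag: str = "HU"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit_tag not in ("HU", "scaled", "dimensionless"):
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}")


@dataclass
class LabelMap:
    """Integer 3D image; labels follow :data:`LOBE_LEGEND`.

    Labels 1-3 form the right lung, 4-5 the left lung, and their union the
    whole-lung mask. A map may also carry only the side labels (1 = right,
    4 = left) when lobes have not been resolved.
    """

    grid: Grid3D
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValidationError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValidationError("labels must be integer-valued")
            self.labels = self.labels.astype(np.int16)
        bad = sorted(set(np.unique(self.labels)) - set(LOBE_LEGEND))
        if bad:
            raise ValidationError(f"labels outside legend: {bad}")

    @property
    def legend(self) -> dict:
        return dict(LOBE_LEGEND)

    def lung_mask(self) -> np.ndarray:
        return self.labels > 0

    def side_mask(self, side: str) -> np.ndarray:
        labels = RIGHT_LABELS if side == "right" else LEFT_LABELS
        return np.isin(self.labels, labels)

    def region_mask(self, region: str) -> np.ndarray:
        if region == "whole":
            return self.lung_mask()
        if region in ("right", "left"):
            return self.side_mask(region)
        for lab, name in LOBE_LEGEND.items():
            if name == region:
                return self.labels == lab
        raise ValidationError(f"unknown region {region!r}")


@dataclass
class SubjectRecord:
    """Per-subject metadata consumed by the cohort statistics layer."""

    subject_id: str
    fibrosis_extent: float  # percent of whole lung, [0, 100]
    pattern_group: str
    fvc_l: float | None = None  # litres; None when missing

    def __post_init__(self):
        self.fibrosis_extent = float(self.fibrosis_extent)
        if not 0.0 <= self.fibrosis_extent <= 100.0:
            raise ValidationError(
                f"{self.subject_id}: fibrosis_extent must be in [0, 100], got {self.fibrosis_extent}"
            )
        if self.pattern_group not in PATTERN_GROUPS:
            raise ValidationError(
                f"{self.subject_id}: unknown pattern_group {self.pattern_group!r}; "
                f"expected one of {PATTERN_GROUPS}"
            )
        if self.fvc_l is not None:
            if isinstance(self.fvc_l, float) and math.isnan(self.fvc_l):
                self.fvc_l = None
            else:
                self.fvc_l = float(self.fvc_l)
                if self.fvc_l <= 0:
                    raise ValidationError(f"{self.subject_id}: fvc_l must be positive")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _check_orthogonal(affine: np.ndarray, path, tol: float = 1e-3) -> None:
    A = affine[:3, :3]
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms <= 0):
        raise OrientationError(f"{path}: degenerate affine (zero-length voxel axis)")
    C = np.abs(A / norms)
    for j in range(3):
        k = int(np.argmax(C[:, j]))
        off = np.delete(C[:, j], k)
        if abs(C[k, j] - 1.0) > tol or np.any(off > tol):
            raise OrientationError(
                f"{path}: oblique acquisition (direction cosines not axis-aligned "
                f"within {tol}); reslice upstream"
            )


def _load_canonical(path):
    """Load a 3D NIfTI and reorient the array into the package convention."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3D dataset, got shape {img.shape}")
    affine = np.asarray(img.affine, dtype=np.float64)
    _check_orthogonal(affine, path)
    ornt = nib.orientations.ornt_transform(
        nib.orientations.io_orientation(affine),
        nib.orientations.axcodes2ornt(_TARGET_AXCODES),
    )
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), ornt)
    aff = affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    spacing = tuple(np.linalg.norm(aff[:3, :3], axis=0))
    # LPS coordinates = (-x, -y, +z) of the NIfTI RAS frame.
    origin = (-aff[0, 3], -aff[1, 3], aff[2, 3])
    grid = Grid3D(data.shape, spacing, origin)
    return data, grid


def _lps_affine(grid: Grid3D) -> np.ndarray:
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    return np.array(
        [
            [-sx, 0.0, 0.0, -ox],
            [0.0, -sy, 0.0, -oy],
            [0.0, 0.0, sz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI scalar volume; returns HU values in package convention."""
    data, grid = _load_canonical(path)
    return Volume3D(grid, np.ascontiguousarray(data, dtype=np.float32), "HU")


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1; the affine encodes spacing/origin (LPS content)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), _lps_affine(vol.grid))
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"failed to write volume to {path}: {exc}") from exc


def read_labelmap(path) -> LabelMap:
    """Read an integer NIfTI label map; labels must lie within the legend."""
    data, grid = _load_canonical(path)
    labels = np.ascontiguousarray(np.round(np.asarray(data)).astype(np.int16))
    bad = sorted(set(np.unique(labels)) - set(LOBE_LEGEND))
    if bad:
        raise ValidationError(f"{path}: labels outside legend: {bad}")
    return LabelMap(grid, labels)


def write_labelmap(lm: LabelMap, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(lm.labels, dtype=np.int16), _lps_affine(lm.grid))
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"failed to write label map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Subject metadata CSV
# ---------------------------------------------------------------------------

_SUBJECT_COLUMNS = ["subject_id", "fibrosis_extent", "pattern_group", "fvc_l"]


def read_subjects(path) -> list:
    """Read per-subject metadata from a UTF-8 CSV with a header row."""
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        fvc = getattr(row, "fvc_l")
        fvc = None if pd.isna(fvc) else float(fvc)
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                fibrosis_extent=float(row.fibrosis_extent),
                pattern_group=str(row.pattern_group),
                fvc_l=fvc,
            )
        )
    return records


def write_subjects(records: Iterable[SubjectRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "fibrosis_extent": r.fibrosis_extent,
            "pattern_group": r.pattern_group,
            "fvc_l": r.fvc_l,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SUBJECT_COLUMNS).to_csv(path, index=False)
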