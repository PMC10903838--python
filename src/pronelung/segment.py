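"""Whole-lung and lobar mask production plus segmentation QC.

The segmenter is a deterministic classical algorithm (threshold, border
clearing, size filter, morphological closing, left/right split). Lobes come
either from geometric fissure planes (the phantom exports its true planes)
or from an externally supplied lobe mask, which is validated against the
lung mask and adopted; on real CT, lobar masks must be external. The QC gate
flags anatomically implausible masks instead of raising, so cohort runs can
exclude subjects the way studies do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import core_io
from .core_io import LabelMap, Volume3D
from .errors import SegmentationFailureError, ValidationError
from .phantom import FissurePlanes, lobes_from_planes
from .qc import QCVerdict


@dataclass(frozen=True)
class SegmentationConfig:
    lung_hu_threshold: float = -320.0
    min_component_ml: float = 100.0
    closing_radius_mm: float = 3.0
    qc_min_lung_ml: float = 1000.0
    qc_max_lung_ml: float = 9000.0
    scaled_divisor: float = 3000.0  # threshold divisor when input is scaled

    def __post_init__(self):
        if not -1024.0 < self.lung_hu_threshold < 0.0:
            raise ValidationError("lung_hu_threshold must be in (-1024, 0)")
        if self.qc_min_lung_ml >= self.qc_max_lung_ml:
            raise ValidationError("qc_min_lung_ml must be below qc_max_lung_ml")


def _ball(radius_mm: float, spacing) -> np.ndarray | None:
    r = [int(np.floor(radius_mm / s)) for s in spacing]
    if max(r) < 1:
        return None
    ax = [np.arange(-n, n + 1) * s for n, s in zip(r, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= radius_mm**2


def _clear_xy_border(binary: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary)
    if n == 0:
        return binary
    border = np.zeros(binary.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    touching = np.unique(lab[border & binary])
    if touching.size:
        binary = binary & ~np.isin(lab, touching)
    return binary


def segment_lungs(vol: Volume3D, cfg: SegmentationConfig | None = None) -> LabelMap:
    """Threshold/morphology lung segmentation.

    Steps: binarize below threshold; drop components touching the x/y grid
    border (exterior air); drop components smaller than ``min_component_ml``;
    morphological closing; split into right (label 1) and left (label 4)
    lungs by component centroids, with a sagittal-profile split when fused.
    Lobes stay unresolved (see :func:`assign_lobes`).
    """
    cfg = cfg or SegmentationConfig()
    thr = cfg.lung_hu_threshold
    if vol.unit_tag == "scaled":
        thr = thr / cfg.scaled_divisor
    binary = np.asarray(vol.values) < thr
    binary = _clear_xy_border(binary)
    lab, n = ndimage.label(binary)
    if n:
        voxvol = vol.grid.voxel_volume_mm3 / 1000.0  # mL
        counts = np.bincount(lab.ravel())
        keep = np.flatnonzero(counts * voxvol >= cfg.min_component_ml)
        keep = keep[keep != 0]
        binary = np.isin(lab, keep)
    ball = _ball(cfg.closing_radius_mm, vol.grid.spacing)
    if ball is not None and binary.any():
        binary = ndimage.binary_closing(binary, structure=ball)
        binary = _clear_xy_border(binary)
    if not binary.any():
        raise SegmentationFailureError("no lung voxels after thresholding and filtering")

    labels = np.zeros(vol.grid.shape, dtype=np.int16)
    comp, n = ndimage.label(binary)
    if n >= 2:
        centx = ndimage.center_of_mass(binary, comp, index=np.arange(1, n + 1))
        mid = float(np.mean([c[0] for c in centx]))
        for i, c in enumerate(centx, start=1):
            labels[comp == i] = 1 if c[0] <= mid else 4
        if not (labels == 1).any() or not (labels == 4).any():
            n = 1  # all components fell on one side; fall through to split
    if n == 1 or not ((labels == 1).any() and (labels == 4).any()):
        # fused lungs: split at the minimum of the x occupancy profile
        profile = binary.sum(axis=(1, 2))
        nx = profile.size
        lo, hi = nx // 3, 2 * nx // 3
        split = lo + int(np.argmin(profile[lo:hi]))
        labels[:] = 0
        idx = np.arange(nx)[:, None, None]
        labels[binary & (idx <= split)] = 1
        labels[binary & (idx > split)] = 4
    return LabelMap(vol.grid, labels)


def assign_lobes(lungs: LabelMap, fissures: FissurePlanes | None = None,
                 external: LabelMap | None = None, min_agreement: float = 0.95) -> LabelMap:
    """Resolve lobes from fissure planes or adopt a validated external map.

    An external lobe map must agree with the lung mask on at least
    ``min_agreement`` (Dice of the binary lung extents); otherwise a QC
    error is raised.
    """
    lung_mask = lungs.lung_mask()
    if not lung_mask.any():
        raise ValidationError("lung mask is empty; nothing to partition")
    if external is not None:
        if not external.grid.approx_equal(lungs.grid):
            raise ValidationError("external lobe map must share the lung-mask grid")
        ext_mask = external.lung_mask()
        denom = int(ext_mask.sum()) + int(lung_mask.sum())
        agreement = 2.0 * int((ext_mask & lung_mask).sum()) / denom if denom else 1.0
        if agreement < min_agreement:
            raise ValidationError(
                f"external lobe map agrees with the lung mask on only "
                f"{agreement:.3f} of the lung extent (< {min_agreement})"
            )
        return LabelMap(lungs.grid, external.labels.copy())
    if fissures is None:
        raise ValidationError("either fissure planes or an external lobe map is required")
    return LabelMap(lungs.grid, lobes_from_planes(lungs.labels, lungs.grid, fissures))


def qc_segmentation(lm: LabelMap, cfg: SegmentationConfig | None = None,
                    expect_lobes: bool | None = None) -> QCVerdict:
    """Plausibility gate mirroring study-style exclusion of bad masks.

    Fails when whole-lung volume falls outside physiologic bounds, when any
    expected lobe is empty, or when the left/right volume ratio is extreme.
    ``expect_lobes=None`` infers lobar maps from the presence of any
    non-side label.
    """
    cfg = cfg or SegmentationConfig()
    voxml = lm.grid.voxel_volume_mm3 / 1000.0
    present = set(np.unique(lm.labels))
    if expect_lobes is None:
        expect_lobes = bool(present & {2, 3, 5})
    reasons = []
    whole_ml = float(lm.lung_mask().sum() * voxml)
    if not cfg.qc_min_lung_ml <= whole_ml <= cfg.qc_max_lung_ml:
        reasons.append(
            f"whole-lung volume {whole_ml:.0f} mL outside "
            f"[{cfg.qc_min_lung_ml:.0f}, {cfg.qc_max_lung_ml:.0f}] mL"
        )
    if expect_lobes:
        for lab in core_io.LUNG_LABELS:
            if lab not in present:
                reasons.append(f"empty lobe: {core_io.LOBE_LEGEND[lab]}")
    left_ml = float(lm.side_mask("left").sum() * voxml)
    right_ml = float(lm.side_mask("right").sum() * voxml)
    if left_ml == 0 or right_ml == 0:
        reasons.append("one lung is empty")
    else:
        ratio = left_ml / right_ml
        if not 0.2 <= ratio <= 5.0:
            reasons.append(f"left/right volume ratio {ratio:.2f} outside [0.2, 5]")
    return QCVerdict(
        passed=not reasons,
        reasons=reasons,
        metrics={"whole_ml": whole_ml, "left_ml": left_ml, "right_ml": right_ml},
    )
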