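"""Per-subject quantification: lobar volumetrics, movement maxima, Dice, QC.

Volumes are measured on each position's own (resampled, pre-registration)
masks, because the affine stage includes scaling and would distort volumes
measured after alignment. Movement is read from the deformable displacement
field over the supine whole-lung mask: per-axis statistics are percentiles
of the absolute components and the 3D statistic is the same percentile of
the Euclidean magnitude, reported in centimetres. The default percentile of
100 is the strict voxel maximum ("maximum pixel movement"); a lower
percentile is available because the pure max is noise-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import core_io
from .core_io import LabelMap, Volume3D
from .errors import ValidationError
from .phantom import FissurePlanes, apply_deformation
from .preprocess import PreprocessConfig, resample_to_cube, scale_attenuation
from .qc import QCVerdict
from .register_affine import AffineOptions, apply_affine, estimate_affine, qc_affine
from .register_deformable import DemonsConfig, DisplacementField, register_deformable
from .segment import SegmentationConfig, assign_lobes, qc_segmentation, segment_lungs

REGIONS = ("whole", "right", "left", "RUL", "RML", "RLL", "LUL", "LLL")
_LOBE_REGIONS = ("RUL", "RML", "RLL", "LUL", "LLL")


def dice(a, b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks count as 1.0."""
    am = a.lung_mask() if isinstance(a, LabelMap) else np.asarray(a, dtype=bool)
    bm = b.lung_mask() if isinstance(b, LabelMap) else np.asarray(b, dtype=bool)
    if am.shape != bm.shape:
        raise ValidationError("dice requires masks of identical shape")
    sa, sb = int(am.sum()), int(bm.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / (sa + sb)


def region_volumes(lm: LabelMap) -> dict:
    """Volume in mL per region: voxel count x voxel volume / 1000."""
    voxml = lm.grid.voxel_volume_mm3 / 1000.0
    counts = np.bincount(lm.labels.ravel(), minlength=6)
    out = {name: float(counts[lab] * voxml) for lab, name in core_io.LOBE_LEGEND.items() if lab > 0}
    out["right"] = out["RUL"] + out["RML"] + out["RLL"]
    out["left"] = out["LUL"] + out["LLL"]
    out["whole"] = out["right"] + out["left"]
    return out


@dataclass
class VolumeReport:
    """Supine/prone/delta volumes (mL) per region; delta = prone - supine."""

    supine_ml: dict
    prone_ml: dict
    delta_ml: dict
    has_lobes: bool = True

    def __post_init__(self):
        for vols in (self.supine_ml, self.prone_ml):
            if abs(vols["whole"] - (vols["right"] + vols["left"])) > 0.005 * max(vols["whole"], 1e-9):
                raise ValidationError("regional volumes do not add up (whole != right + left)")

    def to_dict(self) -> dict:
        return {
            region: {
                "supine_ml": self.supine_ml.get(region),
                "prone_ml": self.prone_ml.get(region),
                "delta_ml": self.delta_ml.get(region),
            }
            for region in REGIONS
            if region in self.delta_ml
        }


def volume_change(supine_lm: LabelMap, prone_lm: LabelMap, require_lobes: bool = True) -> VolumeReport:
    """Prone-minus-supine volume change per region (positive = expansion).

    Measured on each scan's own masks before any registration. With
    ``require_lobes`` every lobe must be non-empty in both maps; a missing
    lobe is a QC condition and raises.
    """
    sup = region_volumes(supine_lm)
    pro = region_volumes(prone_lm)
    has_lobes = all(sup[r] > 0 for r in _LOBE_REGIONS) and all(pro[r] > 0 for r in _LOBE_REGIONS)
    if require_lobes and not has_lobes:
        missing = sorted(
            {r for r in _LOBE_REGIONS if sup[r] == 0 or pro[r] == 0}
        )
        raise ValidationError(f"cannot report lobar volume change; empty lobes: {missing}")
    regions = REGIONS if has_lobes else ("whole", "right", "left")
    return VolumeReport(
        supine_ml={r: sup[r] for r in regions},
        prone_ml={r: pro[r] for r in regions},
        delta_ml={r: pro[r] - sup[r] for r in regions},
        has_lobes=has_lobes,
    )


@dataclass
class MovementSummary:
    max_abs_x_cm: float
    max_abs_y_cm: float
    max_abs_z_cm: float
    max_3d_cm: float
    percentile_used: float = 100.0
    region: tuple = core_io.LUNG_LABELS

    def to_dict(self) -> dict:
        return {
            "max_abs_x_cm": self.max_abs_x_cm,
            "max_abs_y_cm": self.max_abs_y_cm,
            "max_abs_z_cm": self.max_abs_z_cm,
            "max_3d_cm": self.max_3d_cm,
            "percentile_used": self.percentile_used,
        }


def movement_summary(field: DisplacementField, mask: LabelMap, percentile: float = 100.0) -> MovementSummary:
    """Per-axis and 3D Euclidean movement statistics over the lung (cm).

    The 3D statistic is the chosen percentile of sqrt(dx^2+dy^2+dz^2); the
    per-axis statistics are the same percentile of |dx|, |dy|, |dz|.
    """
    if not field.grid.approx_equal(mask.grid):
        raise ValidationError("field and mask must share a grid")
    m = mask.lung_mask()
    if not m.any():
        raise ValidationError("empty mask: no lung voxels to summarize")
    if not 0 < percentile <= 100:
        raise ValidationError("percentile must be in (0, 100]")
    v = np.asarray(field.vectors, dtype=np.float64)[m]
    mags = np.sqrt((v**2).sum(axis=-1))
    px = float(np.percentile(np.abs(v[:, 0]), percentile))
    py = float(np.percentile(np.abs(v[:, 1]), percentile))
    pz = float(np.percentile(np.abs(v[:, 2]), percentile))
    p3 = float(np.percentile(mags, percentile))
    return MovementSummary(px / 10.0, py / 10.0, pz / 10.0, p3 / 10.0, percentile,
                           core_io.LUNG_LABELS)


# ---------------------------------------------------------------------------
# Per-subject pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    preprocess: PreprocessConfig = dc_field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    affine: AffineOptions = dc_field(default_factory=AffineOptions)
    demons: DemonsConfig = dc_field(default_factory=DemonsConfig)
    qc_dice_threshold: float = 0.80
    movement_percentile: float = 100.0


@dataclass
class SubjectResult:
    subject_id: str
    qc_passed: bool
    qc_reasons: list = dc_field(default_factory=list)
    affine_dice: float | None = None
    dice_whole: float | None = None
    dice_right: float | None = None
    dice_left: float | None = None
    volume_report: VolumeReport | None = None
    movement: MovementSummary | None = None
    field: DisplacementField | None = dc_field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "qc_passed": self.qc_passed,
            "qc_reasons": list(self.qc_reasons),
            "affine_dice": self.affine_dice,
            "dice_whole": self.dice_whole,
            "dice_right": self.dice_right,
            "dice_left": self.dice_left,
            "volumes": self.volume_report.to_dict() if self.volume_report else None,
            "movement": self.movement.to_dict() if self.movement else None,
        }


def _warp_mask(mask: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Warp a binary mask through the field (linear + 0.5 threshold)."""
    vol = Volume3D(field.grid, mask.astype(np.float32), "dimensionless")
    warped = apply_deformation(vol, field, "linear", fill=0.0)
    return np.asarray(warped.values) >= 0.5


def analyze_subject(subject_id: str, supine_vol: Volume3D, prone_vol: Volume3D,
                    cfg: AnalysisConfig | None = None,
                    supine_labels: LabelMap | None = None,
                    prone_labels: LabelMap | None = None,
                    fissures: FissurePlanes | None = None,
                    prone_fissures: FissurePlanes | None = None) -> SubjectResult:
    """Run the full single-subject pipeline.

    Order: preprocess (cube resample + attenuation scaling) -> masks
    (external lobe maps when given, else classical segmentation with
    optional fissure planes) -> shear-free affine of the prone mask onto the
    supine mask (+ Dice QC) -> demons deformable registration of the scaled
    volumes -> volumetrics, movement and overlap metrics. QC failures
    produce a failed :class:`SubjectResult`, not an exception; the pipeline
    is deterministic given inputs and configuration.
    """
    cfg = cfg or AnalysisConfig()
    sup = resample_to_cube(supine_vol, cfg.preprocess)
    pro = resample_to_cube(prone_vol, cfg.preprocess)
    if prone_fissures is None:
        prone_fissures = fissures  # planes only valid in both spaces for small pose

    def make_masks(vol, external, planes):
        if external is not None:
            return resample_to_cube(external, cfg.preprocess)
        lungs = segment_lungs(vol, cfg.segmentation)
        if planes is not None:
            return assign_lobes(lungs, fissures=planes)
        return lungs

    try:
        sup_lab = make_masks(sup, supine_labels, fissures)
        pro_lab = make_masks(pro, prone_labels, prone_fissures)
    except Exception as exc:  # segmentation failure is a QC state
        return SubjectResult(subject_id, False, [f"segmentation_failure: {exc}"])

    for name, lab in (("supine", sup_lab), ("prone", pro_lab)):
        verdict = qc_segmentation(lab, cfg.segmentation)
        if not verdict:
            return SubjectResult(
                subject_id, False,
                [f"segmentation_failure ({name}): {r}" for r in verdict.reasons],
            )

    has_lobes = bool(set(np.unique(sup_lab.labels)) & {2, 3, 5}) and bool(
        set(np.unique(pro_lab.labels)) & {2, 3, 5}
    )
    volume_report = volume_change(sup_lab, pro_lab, require_lobes=has_lobes)

    est = estimate_affine(pro_lab, sup_lab, cfg.affine)
    pro_lab_reg = apply_affine(pro_lab, est.transform, sup_lab.grid)
    verdict = qc_affine(sup_lab, pro_lab_reg, cfg.qc_dice_threshold)
    if not verdict:
        return SubjectResult(
            subject_id, False,
            [f"registration_failure: {r}" for r in verdict.reasons],
            affine_dice=verdict.metrics["dice"],
            volume_report=volume_report,
        )

    sup_scaled = scale_attenuation(sup, cfg.preprocess)
    pro_scaled = scale_attenuation(pro, cfg.preprocess)
    pro_scaled_reg = apply_affine(pro_scaled, est.transform, sup.grid)
    demons = register_deformable(sup_scaled, pro_scaled_reg, cfg.demons)
    field = demons.field

    sup_mask = sup_lab.lung_mask()
    reg_whole = _warp_mask(pro_lab_reg.lung_mask(), field)
    reg_right = _warp_mask(pro_lab_reg.side_mask("right"), field)
    reg_left = _warp_mask(pro_lab_reg.side_mask("left"), field)
    movement = movement_summary(field, sup_lab, cfg.movement_percentile)

    return SubjectResult(
        subject_id=subject_id,
        qc_passed=True,
        qc_reasons=[],
        affine_dice=est.dice,
        dice_whole=dice(sup_mask, reg_whole),
        dice_right=dice(sup_lab.side_mask("right"), reg_right),
        dice_left=dice(sup_lab.side_mask("left"), reg_left),
        volume_report=volume_report,
        movement=movement,
        field=field,
    )
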