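"""Cohort orchestration: configuration, per-subject isolation, manifests.

A cohort run processes every subject directory under the input root,
records each QC disposition (pass / segmentation failure / registration
failure / errored) without aborting the run, and writes per-subject JSON
results, a cohort CSV, the report tables and a manifest capturing package
version, configuration hash and seed. Same inputs + config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import AnalysisConfig, SubjectResult, analyze_subject
from .core_io import (
    read_labelmap,
    read_subjects,
    read_volume,
    write_labelmap,
    write_subjects,
    write_volume,
)
from .errors import ConfigError, ProneLungError
from .phantom import CohortModel, FissurePlanes, PhantomSpec, generate_cohort
from .preprocess import PreprocessConfig
from .register_affine import AffineOptions
from .register_deformable import DemonsConfig, export_field
from .segment import SegmentationConfig
from .stats import cohort_tables
from .viz import VizConfig, hsv_movement_map, quiver_map

logger = logging.getLogger("pronelung")


@dataclass
class RunConfig:
    input_dir: str = ""
    output_dir: str = ""
    seed: int = 0
    mask_source: str = "auto"  # auto | external | segment
    qc_dice_threshold: float = 0.80
    exclude_failed: bool = True
    movement_percentile: float = 100.0
    save_fields: bool = False
    make_figures: bool = True
    preprocess: PreprocessConfig = dc_field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    affine: AffineOptions = dc_field(default_factory=AffineOptions)
    demons: DemonsConfig = dc_field(default_factory=DemonsConfig)
    viz: VizConfig = dc_field(default_factory=VizConfig)

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            preprocess=self.preprocess,
            segmentation=self.segmentation,
            affine=self.affine,
            demons=self.demons,
            qc_dice_threshold=self.qc_dice_threshold,
            movement_percentile=self.movement_percentile,
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dc_fields(obj) if f.init}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SUBCONFIGS = {
    "preprocess": PreprocessConfig,
    "segmentation": SegmentationConfig,
    "affine": AffineOptions,
    "demons": DemonsConfig,
    "viz": VizConfig,
}


def _build_dataclass(cls, data: dict, context: str):
    names = {f.name for f in dc_fields(cls) if f.init}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            hint = difflib.get_close_matches(key, sorted(names), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {context}{key!r}{suggestion}")
        fld = next(f for f in dc_fields(cls) if f.name == key)
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError, ProneLungError) as exc:
        raise ConfigError(f"invalid configuration under {context or 'top level'}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    top = {}
    for key, value in data.items():
        if key in _SUBCONFIGS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            top[key] = _build_dataclass(_SUBCONFIGS[key], value, f"{key}.")
        else:
            top[key] = value
    return _build_dataclass(RunConfig, top, "")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    data = yaml.safe_load(text)
    return config_from_dict(data or {})


# ---------------------------------------------------------------------------
# Cohort I/O layout
# ---------------------------------------------------------------------------

def write_simulated_cohort(out_dir, n: int, seed: int = 0,
                           base_spec: PhantomSpec | None = None,
                           model: CohortModel | None = None,
                           save_truth: bool = True) -> None:
    """Write a simulated cohort in the on-disk layout the pipeline reads.

    Per subject: supine/prone volumes and lobe label maps (NIfTI), the true
    fissure planes and pose (JSON) and optionally the ground-truth field
    (4D NIfTI); plus a cohort-level subjects.csv.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(n, model=model, seed=seed, base_spec=base_spec)
    records = []
    for pair, record in cohort:
        sdir = out_dir / record.subject_id
        sdir.mkdir(exist_ok=True)
        write_volume(pair.supine_vol, sdir / "supine.nii.gz")
        write_volume(pair.prone_vol, sdir / "prone.nii.gz")
        write_labelmap(pair.supine_labels, sdir / "supine_labels.nii.gz")
        write_labelmap(pair.prone_labels, sdir / "prone_labels.nii.gz")
        (sdir / "fissures.json").write_text(json.dumps(pair.fissures.to_dict(), indent=2))
        (sdir / "prone_fissures.json").write_text(
            json.dumps(pair.prone_fissures.to_dict(), indent=2)
        )
        if save_truth:
            pair.true_pose.save(sdir / "true_pose.json")
            export_field(pair.true_field, sdir / "true_field.nii.gz")
        records.append(record)
    write_subjects(records, out_dir / "subjects.csv")


def _load_subject_inputs(sdir: Path, mask_source: str):
    supine = read_volume(sdir / "supine.nii.gz")
    prone = read_volume(sdir / "prone.nii.gz")
    kwargs = {}
    have_external = (sdir / "supine_labels.nii.gz").exists() and (sdir / "prone_labels.nii.gz").exists()
    if mask_source == "external" or (mask_source == "auto" and have_external):
        kwargs["supine_labels"] = read_labelmap(sdir / "supine_labels.nii.gz")
        kwargs["prone_labels"] = read_labelmap(sdir / "prone_labels.nii.gz")
    fiss_path = sdir / "fissures.json"
    if fiss_path.exists():
        kwargs["fissures"] = FissurePlanes.from_dict(json.loads(fiss_path.read_text()))
    pf_path = sdir / "prone_fissures.json"
    if pf_path.exists():
        kwargs["prone_fissures"] = FissurePlanes.from_dict(json.loads(pf_path.read_text()))
    return supine, prone, kwargs


def _result_row(res: SubjectResult, status: str) -> dict:
    row = {"subject_id": res.subject_id, "qc_status": status,
           "qc_reasons": "; ".join(res.qc_reasons)}
    for region in ("whole", "right", "left", "RUL", "RML", "RLL", "LUL", "LLL"):
        for kind in ("supine_ml", "prone_ml", "delta_ml"):
            key = f"{region}_{kind}"
            if res.volume_report is not None and region in res.volume_report.delta_ml:
                row[key] = round(getattr(res.volume_report, kind)[region], 3)
            else:
                row[key] = np.nan
    for key in ("max_abs_x_cm", "max_abs_y_cm", "max_abs_z_cm", "max_3d_cm"):
        row[key] = round(getattr(res.movement, key), 4) if res.movement else np.nan
    for key in ("affine_dice", "dice_whole", "dice_right", "dice_left"):
        v = getattr(res, key)
        row[key] = round(v, 4) if v is not None else np.nan
    return row


def _classify(res: SubjectResult) -> str:
    if res.qc_passed:
        return "pass"
    for reason in res.qc_reasons:
        if reason.startswith("registration_failure"):
            return "registration_failure"
        if reason.startswith("segmentation_failure"):
            return "segmentation_failure"
    return "errored"


def run_cohort(config: RunConfig) -> dict:
    """Run the full pipeline over every subject directory under input_dir.

    Per-subject hard errors (unreadable files, etc.) mark that subject
    ``errored`` and the run continues; the returned manifest accounts for
    every subject: subjects_in = pass + registration_failure +
    segmentation_failure + errored.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    if not in_dir.is_dir():
        raise ConfigError(f"input_dir {in_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "subjects").mkdir(exist_ok=True)
    subjects = read_subjects(in_dir / "subjects.csv")
    acfg = config.analysis_config()

    results = []
    counts = {"pass": 0, "registration_failure": 0, "segmentation_failure": 0, "errored": 0}
    rows = []
    figure_done = False
    for record in subjects:
        sdir = in_dir / record.subject_id
        try:
            supine, prone, kwargs = _load_subject_inputs(sdir, config.mask_source)
            if config.mask_source == "segment":
                kwargs.pop("supine_labels", None)
                kwargs.pop("prone_labels", None)
            res = analyze_subject(record.subject_id, supine, prone, acfg, **kwargs)
            status = _classify(res)
        except Exception as exc:  # hard error: isolate the subject
            logger.warning("subject %s errored: %s", record.subject_id, exc)
            res = SubjectResult(record.subject_id, False, [f"error: {exc}"])
            status = "errored"
        counts[status] += 1
        results.append(res)
        rows.append(_result_row(res, status))
        (out_dir / "subjects" / f"{record.subject_id}.json").write_text(
            json.dumps(res.to_dict(), indent=2, sort_keys=True)
        )
        if res.field is not None and config.save_fields:
            export_field(res.field, out_dir / "subjects" / f"{record.subject_id}_field.nii.gz")
        if res.field is not None and config.make_figures and not figure_done:
            figdir = out_dir / "figures"
            figdir.mkdir(exist_ok=True)
            # masks live on the preprocessed grid; regenerate them cheaply
            from .preprocess import resample_to_cube

            mask = kwargs.get("supine_labels")
            mask = resample_to_cube(mask, config.preprocess) if mask is not None else None
            if mask is not None:
                hsv_movement_map(res.field, mask, config.viz,
                                 background=resample_to_cube(supine, config.preprocess),
                                 out_path=figdir / f"{record.subject_id}_hsv.png")
                quiver_map(res.field, mask, config.viz,
                           out_path=figdir / f"{record.subject_id}_quiver.png")
            figure_done = True

    cohort_df = pd.DataFrame(rows)
    cohort_df.to_csv(out_dir / "cohort.csv", index=False)
    tables = cohort_tables(results, subjects)
    tdir = out_dir / "tables"
    tdir.mkdir(exist_ok=True)
    for name, df in tables.items():
        df.to_csv(tdir / f"{name}.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "subjects_in": len(subjects),
        "counts": counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"manifest": manifest, "results": results, "tables": tables}
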