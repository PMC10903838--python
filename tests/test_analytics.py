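import numpy as np
import pytest

from pronelung import DisplacementField, Grid3D, LabelMap
from pronelung.analytics import (
    AnalysisConfig,
    analyze_subject,
    dice,
    movement_summary,
    region_volumes,
    volume_change,
)
from pronelung.errors import ValidationError
from pronelung.preprocess import PreprocessConfig


def _lm(grid, labels):
    return LabelMap(grid, np.asarray(labels, dtype=np.int16))


def _five_lobe_map(grid):
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[2:4, 2:4, 2:4] = 1
    labels[4:6, 2:4, 2:4] = 2
    labels[6:8, 2:4, 2:4] = 3
    labels[2:4, 6:8, 2:4] = 4
    labels[4:6, 6:8, 2:4] = 5
    return LabelMap(grid, labels)


class TestRegionVolumes:
    def test_unit_spacing(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        labels = np.zeros(grid.shape, dtype=np.int16)
        labels.ravel()[:1000] = 1
        vols = region_volumes(_lm(grid, labels))
        assert vols["RUL"] == pytest.approx(1.0)
        assert vols["whole"] == pytest.approx(1.0)

    def test_two_mm_spacing(self):
        grid = Grid3D((10, 10, 10), (2.0, 2.0, 2.0))
        labels = np.zeros(grid.shape, dtype=np.int16)
        labels.ravel()[:1000] = 3
        vols = region_volumes(_lm(grid, labels))
        assert vols["RLL"] == pytest.approx(8.0)

    def test_phantom_matches_direct_count(self, small_pair):
        vols = region_volumes(small_pair.supine_labels)
        voxml = small_pair.supine_labels.grid.voxel_volume_mm3 / 1000.0
        direct = (small_pair.supine_labels.labels == 3).sum() * voxml
        assert vols["RLL"] == pytest.approx(direct, abs=voxml)

    def test_additivity(self, small_pair):
        vols = region_volumes(small_pair.supine_labels)
        assert vols["whole"] == pytest.approx(vols["right"] + vols["left"], rel=0.005)
        assert vols["right"] == pytest.approx(vols["RUL"] + vols["RML"] + vols["RLL"], rel=0.005)
        assert vols["left"] == pytest.approx(vols["LUL"] + vols["LLL"], rel=0.005)


class TestVolumeChange:
    def test_identical_maps_zero_delta(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        lm = _five_lobe_map(grid)
        report = volume_change(lm, lm)
        assert all(v == 0.0 for v in report.delta_ml.values())

    def test_sign_convention_prone_minus_supine(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        sup = _five_lobe_map(grid)
        labels = sup.labels.copy()
        labels[6:8, 2:4, 4:6] = 3  # prone RLL grows
        report = volume_change(sup, _lm(grid, labels))
        assert report.delta_ml["RLL"] > 0

    def test_missing_lobe_is_flagged(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        sup = _five_lobe_map(grid)
        labels = sup.labels.copy()
        labels[labels == 2] = 0  # prone loses RML
        with pytest.raises(ValidationError, match="RML"):
            volume_change(sup, _lm(grid, labels))


class TestMovementSummary:
    def _single_voxel(self, vec):
        grid = Grid3D((6, 6, 6), (1.0, 1.0, 1.0))
        labels = np.zeros(grid.shape, dtype=np.int16)
        labels[3, 3, 3] = 1
        field = np.zeros(grid.shape + (3,), dtype=np.float32)
        field[3, 3, 3] = vec
        return DisplacementField(grid, field), _lm(grid, labels)

    def test_three_four_five_triangle(self):
        field, mask = self._single_voxel((30.0, 40.0, 0.0))
        ms = movement_summary(field, mask)
        assert (ms.max_abs_x_cm, ms.max_abs_y_cm, ms.max_abs_z_cm) == (3.0, 4.0, 0.0)
        assert ms.max_3d_cm == pytest.approx(5.0)

    def test_zero_field(self):
        field, mask = self._single_voxel((0.0, 0.0, 0.0))
        ms = movement_summary(field, mask)
        assert ms.max_3d_cm == 0.0

    def test_max3d_dominates_axes_and_percentiles_are_ordered(self, small_pair):
        ms100 = movement_summary(small_pair.true_field, small_pair.supine_labels, 100)
        ms95 = movement_summary(small_pair.true_field, small_pair.supine_labels, 95)
        assert ms100.max_3d_cm >= max(ms100.max_abs_x_cm, ms100.max_abs_y_cm, ms100.max_abs_z_cm)
        for attr in ("max_abs_x_cm", "max_abs_y_cm", "max_abs_z_cm", "max_3d_cm"):
            assert getattr(ms95, attr) <= getattr(ms100, attr)

    def test_invariant_to_lobe_relabelling(self, small_pair):
        sides = small_pair.supine_labels.labels.copy()
        sides[np.isin(sides, (2, 3))] = 1
        sides[sides == 5] = 4
        ms_lobes = movement_summary(small_pair.true_field, small_pair.supine_labels)
        ms_sides = movement_summary(small_pair.true_field,
                                    _lm(small_pair.supine_labels.grid, sides))
        assert ms_lobes == ms_sides

    def test_empty_mask_rejected(self):
        field, mask = self._single_voxel((1.0, 0.0, 0.0))
        empty = _lm(mask.grid, np.zeros(mask.grid.shape))
        with pytest.raises(ValidationError):
            movement_summary(field, empty)


class TestDice:
    def test_half_overlap(self):
        # |A| = |B| = 100, overlap 50 -> Dice 0.5
        a = np.zeros((200,), dtype=bool)
        b = np.zeros((200,), dtype=bool)
        a[:100] = True
        b[50:150] = True
        assert dice(a.reshape(10, 10, 2), b.reshape(10, 10, 2)) == pytest.approx(0.5)

    def test_identical_and_disjoint_and_empty(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[:2] = True
        assert dice(m, m) == 1.0
        assert dice(m, ~m) == 0.0
        empty = np.zeros((4, 4, 4), dtype=bool)
        assert dice(empty, empty) == 1.0


class TestAnalyzeSubject:
    def test_end_to_end_populates_everything_and_is_deterministic(self, small_pair, analysis_cfg_48):
        res1 = analyze_subject("S1", small_pair.supine_vol, small_pair.prone_vol,
                               analysis_cfg_48, fissures=small_pair.fissures)
        res2 = analyze_subject("S1", small_pair.supine_vol, small_pair.prone_vol,
                               analysis_cfg_48, fissures=small_pair.fissures)
        assert res1.qc_passed
        assert res1.volume_report is not None and res1.movement is not None
        assert res1.dice_whole is not None and 0 < res1.dice_whole <= 1
        assert res1.to_dict() == res2.to_dict()

    def test_failed_affine_qc_skips_analytics(self, small_pair, analysis_cfg_48):
        import dataclasses

        strict = dataclasses.replace(analysis_cfg_48, qc_dice_threshold=0.999)
        res = analyze_subject("S1", small_pair.supine_vol, small_pair.prone_vol,
                              strict, fissures=small_pair.fissures)
        assert not res.qc_passed
        assert any(r.startswith("registration_failure") for r in res.qc_reasons)
        assert res.movement is None

    def test_segmentation_failure_is_reported_not_raised(self, analysis_cfg_48):
        from pronelung import Volume3D

        grid = Grid3D((48, 48, 48), (6.0, 6.0, 6.0))
        body = Volume3D(grid, np.full(grid.shape, 40.0, dtype=np.float32), "HU")
        res = analyze_subject("S1", body, body, analysis_cfg_48)
        assert not res.qc_passed
        assert any(r.startswith("segmentation_failure") for r in res.qc_reasons)
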