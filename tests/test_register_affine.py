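import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pronelung import AffineTransform, Grid3D, LabelMap, Volume3D
from pronelung.analytics import dice
from pronelung.errors import ValidationError
from pronelung.phantom import PhantomSpec, PoseParams, generate_phantom_pair
from pronelung.register_affine import (
    AffineOptions,
    apply_affine,
    estimate_affine,
    qc_affine,
)
from pronelung.segment import segment_lungs


def _pose_pair(pose, seed=3, noise=20.0):
    spec = PhantomSpec(shape=(48, 48, 48), spacing_mm=(6.0, 6.0, 6.0), seed=seed,
                       deformation_amplitude_mm=0.0, pose=pose, noise_sd_hu=noise)
    return generate_phantom_pair(spec)


class TestTransformAlgebra:
    @settings(max_examples=25, deadline=None)
    @given(
        t=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
        e=st.tuples(*[st.floats(-30, 30) for _ in range(3)]),
        s=st.floats(0.8, 1.25),
    )
    def test_no_shear_decomposition_is_exact(self, t, e, s):
        T = AffineTransform.from_params(t, e, s, (10.0, 20.0, 30.0))
        assert T.decomposition_residual() < 1e-6

    def test_inverse_roundtrip_on_points(self):
        T = AffineTransform.from_params((5, -3, 2), (4, -6, 8), 1.03, (50, 50, 50))
        pts = np.random.default_rng(0).uniform(0, 100, (20, 3))
        back = T.inverse().apply_points(T.apply_points(pts))
        assert np.allclose(back, pts, atol=1e-8)

    def test_json_roundtrip(self, tmp_path):
        T = AffineTransform.from_params((1, 2, 3), (4, 5, 6), 1.01, (0, 0, 0))
        T.save(tmp_path / "t.json")
        back = AffineTransform.load(tmp_path / "t.json")
        assert np.allclose(back.translation, T.translation)
        assert np.allclose(back.rotation, T.rotation)
        assert np.allclose(back.scale, T.scale)
        assert np.allclose(back.center, T.center)


class TestEstimate:
    def test_identical_masks_give_identity(self, small_pair):
        res = estimate_affine(small_pair.supine_labels, small_pair.supine_labels)
        T = res.transform
        assert np.linalg.norm(T.translation) < 0.1
        assert np.max(np.abs(T.euler_deg)) < 0.1
        assert np.max(np.abs(np.asarray(T.scale) - 1.0)) < 1e-3
        assert res.dice == 1.0

    def test_pure_translation_recovered(self):
        pair = _pose_pair(PoseParams(translation_mm=(5.0, -3.0, 2.0)))
        res = estimate_affine(pair.prone_labels, pair.supine_labels)
        expected = pair.true_pose.inverse().translation
        err_vox = np.abs(np.asarray(res.transform.translation) - expected) / 6.0
        assert np.all(err_vox < 0.5)

    def test_scale_and_rotation_recovered(self):
        pair = _pose_pair(PoseParams(rotation_deg=(0.0, 0.0, 6.0), scale=1.03))
        res = estimate_affine(pair.prone_labels, pair.supine_labels)
        Ti = pair.true_pose.inverse()
        assert abs(res.transform.scale[0] - Ti.scale[0]) < 0.01
        assert abs(res.transform.euler_deg[2] - Ti.euler_deg[2]) < 1.0

    def test_refinement_never_degrades_dice(self, small_pair):
        sup = segment_lungs(small_pair.supine_vol)
        pro = segment_lungs(small_pair.prone_vol)
        res = estimate_affine(pro, sup)
        assert res.dice >= res.init_dice

    def test_empty_mask_rejected(self, small_pair):
        empty = LabelMap(small_pair.supine_labels.grid,
                         np.zeros(small_pair.supine_labels.grid.shape, dtype=np.int16))
        with pytest.raises(ValidationError):
            estimate_affine(empty, small_pair.supine_labels)


class TestApply:
    def test_identity_same_grid_returns_input(self, small_pair):
        T = AffineTransform.identity()
        out = apply_affine(small_pair.supine_vol, T, small_pair.supine_vol.grid)
        assert np.array_equal(out.values, small_pair.supine_vol.values)

    def test_translation_moves_delta_spike(self, unit_grid):
        vals = np.zeros(unit_grid.shape, dtype=np.float32)
        vals[8, 8, 8] = 1.0
        vol = Volume3D(unit_grid, vals, "HU")
        T = AffineTransform.from_params((5.0, 0.0, 0.0), (0, 0, 0), 1.0, (0, 0, 0))
        out = apply_affine(vol, T, unit_grid)
        # out(p) = in(p + 5 x) so the spike lands at index 3
        assert out.values[3, 8, 8] == 1.0

    def test_forward_inverse_roundtrip_dice(self, small_pair):
        T = AffineTransform.from_params((6, -4, 3), (5, -4, 6), 1.02,
                                        small_pair.supine_labels.grid.center_mm)
        lm = small_pair.supine_labels
        fwd = apply_affine(lm, T, lm.grid)
        back = apply_affine(fwd, T.inverse(), lm.grid)
        assert dice(lm, back) >= 0.98


class TestQCAffine:
    def test_verdicts(self, small_pair):
        lm = small_pair.supine_labels
        good = qc_affine(lm, lm)
        assert good.passed and good.metrics["dice"] == 1.0
        empty = LabelMap(lm.grid, np.zeros(lm.grid.shape, dtype=np.int16))
        bad = qc_affine(lm, empty)
        assert not bad.passed and bad.metrics["dice"] == 0.0
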