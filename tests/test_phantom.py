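import dataclasses

import numpy as np
import pytest

from pronelung import DisplacementField, Grid3D, LabelMap, Volume3D
from pronelung._field_math import jacobian_determinant_array
from pronelung.errors import GridMismatchError, SpecError, ValidationError
from pronelung.phantom import (
    CohortModel,
    PhantomSpec,
    PoseParams,
    apply_deformation,
    draw_cohort_plan,
    generate_cohort,
    generate_phantom_pair,
)


class TestSpecValidation:
    def test_infeasible_fibrosis(self):
        with pytest.raises(SpecError):
            PhantomSpec(fibrosis_extent=0.99).validate()

    def test_hu_range(self):
        with pytest.raises(SpecError):
            PhantomSpec(lung_hu=-2000).validate()


class TestGeneration:
    def test_identity_composition_gives_equal_pair(self):
        spec = PhantomSpec(
            shape=(40, 40, 40), spacing_mm=(7.2, 7.2, 7.2), seed=1,
            deformation_amplitude_mm=0.0, pose=PoseParams(), noise_sd_hu=0.0,
        )
        pair = generate_phantom_pair(spec)
        assert np.array_equal(pair.prone_vol.values, pair.supine_vol.values)
        assert np.array_equal(pair.prone_labels.labels, pair.supine_labels.labels)
        assert float(pair.true_field.magnitude().max()) == 0.0

    def test_seeded_determinism(self):
        spec = PhantomSpec(shape=(40, 40, 40), spacing_mm=(7.2, 7.2, 7.2), seed=7)
        a = generate_phantom_pair(spec)
        b = generate_phantom_pair(spec)
        assert np.array_equal(a.supine_vol.values, b.supine_vol.values)
        assert np.array_equal(a.prone_vol.values, b.prone_vol.values)
        assert np.array_equal(a.true_field.vectors, b.true_field.vectors)
        assert a.true_pose.to_dict() == b.true_pose.to_dict()

    def test_all_lobes_present_in_both_positions(self, small_pair):
        for lm in (small_pair.supine_labels, small_pair.prone_labels):
            assert set(np.unique(lm.labels)) == {0, 1, 2, 3, 4, 5}

    def test_true_field_peak_matches_amplitude(self, clean_pair):
        peak = float(clean_pair.true_field.magnitude().max())
        assert peak == pytest.approx(clean_pair.spec.deformation_amplitude_mm, rel=0.01)

    def test_field_is_diffeomorphic_in_lung(self, small_pair):
        det = jacobian_determinant_array(
            small_pair.true_field.vectors, small_pair.true_field.grid.spacing
        )
        assert det[small_pair.supine_labels.lung_mask()].min() > 0

    def test_fibrosis_damping_caps_field_at_fibrotic_voxels(self):
        base = dict(shape=(48, 48, 48), spacing_mm=(6.0, 6.0, 6.0), seed=5)
        damped = generate_phantom_pair(
            PhantomSpec(fibrosis_extent=0.5, damping=0.8, **base)
        )
        free = generate_phantom_pair(PhantomSpec(fibrosis_extent=0.0, **base))
        fib = (
            damped.supine_vol.values != free.supine_vol.values
        )  # fibrotic voxels differ in attenuation
        fib &= damped.supine_labels.lung_mask()
        assert fib.any()
        mag_damped = damped.true_field.magnitude()[fib]
        mag_free = free.true_field.magnitude()[fib]
        # float32 storage: allow rounding at the last digit
        assert mag_damped.max() <= 0.2 * mag_free.max() * (1 + 1e-6) + 1e-6


class TestApplyDeformation:
    def test_zero_field_is_identity(self, clean_pair):
        field = DisplacementField(
            clean_pair.supine_vol.grid,
            np.zeros(clean_pair.supine_vol.grid.shape + (3,), dtype=np.float32),
        )
        out = apply_deformation(clean_pair.supine_vol, field)
        assert np.array_equal(out.values, clean_pair.supine_vol.values)

    def test_uniform_field_shifts_delta_spike(self, unit_grid):
        vals = np.zeros(unit_grid.shape, dtype=np.float32)
        vals[8, 8, 8] = 100.0
        vol = Volume3D(unit_grid, vals, "HU")
        vec = np.zeros(unit_grid.shape + (3,), dtype=np.float32)
        vec[..., 0] = 5.0
        out = apply_deformation(vol, DisplacementField(unit_grid, vec), "linear", fill=0.0)
        # out(p) = in(p + 5 x): the spike lands 5 voxels toward -x
        assert out.values[3, 8, 8] == 100.0
        assert out.values.sum() == 100.0

    def test_nearest_warp_of_labels_stays_in_legend(self, small_pair):
        out = apply_deformation(small_pair.supine_labels, small_pair.true_field, "nearest")
        assert set(np.unique(out.labels)) <= {0, 1, 2, 3, 4, 5}

    def test_grid_mismatch_rejected(self, clean_pair, unit_grid):
        field = DisplacementField(unit_grid, np.zeros(unit_grid.shape + (3,), dtype=np.float32))
        with pytest.raises(GridMismatchError):
            apply_deformation(clean_pair.supine_vol, field)


class TestCohort:
    def test_determinism(self):
        base = PhantomSpec(shape=(40, 40, 40), spacing_mm=(7.2, 7.2, 7.2))
        a = generate_cohort(2, seed=1, base_spec=base)
        b = generate_cohort(2, seed=1, base_spec=base)
        for (pa, ra), (pb, rb) in zip(a, b):
            assert ra == rb
            assert pa.spec == pb.spec
            assert np.array_equal(pa.prone_vol.values, pb.prone_vol.values)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(1)

    def test_fibrosis_amplitude_coupling_is_negative(self):
        plan = draw_cohort_plan(50, seed=1)
        ext = np.array([p["fibrosis_extent_pct"] for p in plan])
        amp = np.array([p["deformation_amplitude_mm"] for p in plan])
        assert np.corrcoef(ext, amp)[0, 1] < 0

    def test_zero_slope_gives_flat_amplitude_across_strata(self):
        model = CohortModel(amp_slope_mm_per_pct=0.0, amp_sd_mm=0.0)
        plan = draw_cohort_plan(40, model=model, seed=2)
        amps = {p["deformation_amplitude_mm"] for p in plan}
        assert amps == {model.amp_intercept_mm}
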