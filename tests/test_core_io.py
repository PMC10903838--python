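import nibabel as nib
import numpy as np
import pytest

from pronelung import (
    Grid3D,
    LabelMap,
    SubjectRecord,
    Volume3D,
    read_labelmap,
    read_subjects,
    read_volume,
    write_labelmap,
    write_subjects,
    write_volume,
)
from pronelung.errors import FormatError, OrientationError, ValidationError


def _random_volume(seed=0, shape=(10, 12, 14), spacing=(1.0, 1.0, 3.0)):
    rng = np.random.default_rng(seed)
    grid = Grid3D(shape, spacing, (2.0, -5.0, 10.0))
    return Volume3D(grid, rng.normal(0, 100, shape).astype(np.float32), "HU")


class TestGrid:
    def test_validation(self):
        with pytest.raises(ValidationError):
            Grid3D((1, 4, 4), (1, 1, 1))
        with pytest.raises(ValidationError):
            Grid3D((4, 4, 4), (1, 0, 1))

    def test_extent_and_voxel_volume(self):
        g = Grid3D((10, 10, 10), (1.0, 2.0, 3.0))
        assert g.extent_mm == (10.0, 20.0, 30.0)
        assert g.voxel_volume_mm3 == 6.0


class TestVolumeRoundTrip:
    def test_values_and_spacing_bit_identical(self, tmp_path):
        vol = _random_volume()
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        assert back.grid.shape == vol.grid.shape
        assert np.array_equal(back.values, vol.values)
        assert back.grid.spacing == (1.0, 1.0, 3.0)
        assert np.allclose(back.grid.origin, vol.grid.origin)

    def test_4d_file_rejected(self, tmp_path):
        path = tmp_path / "fourd.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)), str(path))
        with pytest.raises(FormatError):
            read_volume(path)

    def test_oblique_rejected(self, tmp_path):
        aff = np.eye(4)
        aff[0, 1] = 0.3  # sheared voxel axes
        path = tmp_path / "oblique.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.float32), aff), str(path))
        with pytest.raises(OrientationError):
            read_volume(path)

    def test_unwritable_path(self):
        vol = _random_volume()
        with pytest.raises(OSError):
            write_volume(vol, "/proc/definitely/not/writable.nii.gz")


@pytest.mark.parametrize("axcodes", [("L", "P", "S"), ("R", "A", "S"), ("L", "P", "I"), ("S", "P", "L"), ("A", "R", "I")])
def test_any_storage_orientation_reads_to_same_patient_content(tmp_path, axcodes):
    """Files stored with permuted/flipped axes read back into identical
    in-convention arrays, because the affine carries the anatomy."""
    vol = _random_volume(seed=3)
    canonical = tmp_path / "canon.nii.gz"
    write_volume(vol, canonical)
    img = nib.load(str(canonical))
    ornt = nib.orientations.ornt_transform(
        nib.orientations.io_orientation(img.affine),
        nib.orientations.axcodes2ornt(axcodes),
    )
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), ornt)
    aff = img.affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    alt = tmp_path / "alt.nii.gz"
    nib.save(nib.Nifti1Image(data, aff), str(alt))

    back = read_volume(alt)
    assert np.array_equal(back.values, vol.values)
    assert np.allclose(back.grid.spacing, vol.grid.spacing)
    assert np.allclose(back.grid.origin, vol.grid.origin)


class TestLabelMap:
    def test_roundtrip(self, tmp_path, small_pair):
        path = tmp_path / "lab.nii.gz"
        write_labelmap(small_pair.supine_labels, path)
        back = read_labelmap(path)
        assert np.array_equal(back.labels, small_pair.supine_labels.labels)

    def test_label_outside_legend_named(self, tmp_path):
        arr = np.zeros((4, 4, 4), dtype=np.int16)
        arr[1, 1, 1] = 9
        path = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(arr, np.diag([-1.0, -1.0, 1.0, 1.0])), str(path))
        with pytest.raises(ValidationError, match="9"):
            read_labelmap(path)

    def test_empty_labelmap_is_legal(self, tmp_path):
        path = tmp_path / "empty.nii.gz"
        nib.save(
            nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.int16), np.diag([-1.0, -1.0, 1.0, 1.0])),
            str(path),
        )
        lm = read_labelmap(path)
        assert not lm.lung_mask().any()


class TestSubjects:
    def test_roundtrip_and_parsing(self, tmp_path):
        path = tmp_path / "subjects.csv"
        path.write_text(
            "subject_id,fibrosis_extent,pattern_group,fvc_l\n"
            "S1,30,UIP_or_probable,2.8\n"
            "S2,0,normal,\n"
        )
        recs = read_subjects(path)
        assert recs[0].fibrosis_extent == 30.0
        assert recs[0].fvc_l == 2.8
        assert recs[1].fvc_l is None
        out = tmp_path / "out.csv"
        write_subjects(recs, out)
        assert [r.subject_id for r in read_subjects(out)] == ["S1", "S2"]

    def test_extent_out_of_range(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,fibrosis_extent,pattern_group,fvc_l\nS1,110,normal,2.0\n")
        with pytest.raises(ValidationError):
            read_subjects(path)

    def test_unknown_pattern_group(self):
        with pytest.raises(ValidationError):
            SubjectRecord("S1", 10.0, "something_else")
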