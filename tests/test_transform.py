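import numpy as np
import pytest

from morphcascade.transform import (DisplacementField, accumulate_fields,
                                    compose_fields, jacobian_report,
                                    read_field, warp_labels, warp_volume,
                                    write_field)
from morphcascade.volume_io import LabelMap, Volume, VolumeError


def constant_field(shape, vec):
    v = np.zeros((3,) + shape, dtype=np.float32)
    for i, c in enumerate(vec):
        v[i] = c
    return DisplacementField(v)


def ramp_volume(n=8, axis=0):
    idx = np.indices((n, n, n), dtype=np.float64)[axis]
    return Volume(idx)


class TestWarpVolume:
    def test_zero_field_is_identity(self, rng):
        vol = Volume(rng.random((6, 6, 6)))
        out = warp_volume(vol, DisplacementField.zeros((6, 6, 6)))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-7)

    def test_integer_shift_on_ramp(self):
        vol = ramp_volume(8)
        out = warp_volume(vol, constant_field((8, 8, 8), (1, 0, 0)))
        # interior: output(x) = moving(x+1) = x+1 on the ramp
        np.testing.assert_allclose(out.data[:-1], vol.data[:-1] + 1.0,
                                   atol=1e-6)

    def test_half_voxel_shift_is_neighbour_average(self):
        vol = ramp_volume(8)
        out = warp_volume(vol, constant_field((8, 8, 8), (0.5, 0, 0)))
        np.testing.assert_allclose(out.data[:-1], vol.data[:-1] + 0.5,
                                   atol=1e-6)

    def test_linear_warp_preserves_range(self, pair32):
        fixed, moving, _, _, truth = pair32
        out = warp_volume(moving, truth)
        assert out.data.min() >= moving.data.min() - 1e-6
        assert out.data.max() <= moving.data.max() + 1e-6

    def test_constant_volume_preserved(self):
        vol = Volume(np.full((8, 8, 8), 0.3))
        field = constant_field((8, 8, 8), (1.7, -0.4, 0.2))
        np.testing.assert_allclose(warp_volume(vol, field).data, 0.3,
                                   atol=1e-7)

    def test_shape_mismatch_and_bad_mode(self, small_volume):
        field = DisplacementField.zeros((4, 4, 4))
        with pytest.raises(VolumeError):
            warp_volume(small_volume, field)
        with pytest.raises(ValueError, match="interpolation"):
            warp_volume(small_volume, DisplacementField.zeros((10, 10, 10)),
                        interpolation="cubic")


class TestWarpLabels:
    def test_zero_field_identity(self, phantom32):
        _, lab = phantom32
        out = warp_labels(lab, DisplacementField.zeros(lab.shape))
        np.testing.assert_array_equal(out.data, lab.data)

    def test_integer_shift(self):
        data = np.zeros((8, 8, 8), dtype=np.uint8)
        data[4, 4, 4] = 3
        lab = LabelMap(data)
        out = warp_labels(lab, constant_field((8, 8, 8), (1, 0, 0)))
        assert out.data[3, 4, 4] == 3

    def test_no_new_classes_under_smooth_field(self, phantom32,
                                               smooth_field16):
        vol, lab = phantom32
        from morphcascade.phantom import DeformationSpec, make_smooth_field
        field = make_smooth_field(DeformationSpec(size=32, max_disp=3.0,
                                                  smoothness_sigma=2.0,
                                                  seed=1))
        out = warp_labels(lab, field)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))


class TestAccumulate:
    def test_single_field_unchanged(self, smooth_field16):
        out = accumulate_fields([smooth_field16])
        np.testing.assert_array_equal(out.vectors, smooth_field16.vectors)

    def test_field_plus_negation_is_zero(self, smooth_field16):
        neg = DisplacementField(-smooth_field16.vectors)
        out = accumulate_fields([smooth_field16, neg])
        np.testing.assert_allclose(out.vectors, 0.0, atol=1e-6)

    def test_constant_fields_add(self):
        shape = (5, 5, 5)
        out = accumulate_fields([constant_field(shape, v) for v in
                                 [(1, 0, 0), (0, 2, 0), (0, 0, -1)]])
        assert tuple(out.vectors[:, 2, 2, 2]) == (1.0, 2.0, -1.0)

    def test_commutative(self, smooth_field16):
        other = DisplacementField(np.roll(smooth_field16.vectors, 3, axis=1))
        ab = accumulate_fields([smooth_field16, other])
        ba = accumulate_fields([other, smooth_field16])
        np.testing.assert_allclose(ab.vectors, ba.vectors, atol=1e-6)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            accumulate_fields([])


class TestCompose:
    def test_single_field_unchanged(self, smooth_field16):
        out = compose_fields([smooth_field16])
        np.testing.assert_allclose(out.vectors, smooth_field16.vectors,
                                   atol=1e-6)

    def test_constant_fields_compose_to_sum(self):
        shape = (6, 6, 6)
        a = constant_field(shape, (0.5, 0, 0))
        b = constant_field(shape, (0, -0.25, 0.75))
        out = compose_fields([a, b])
        acc = accumulate_fields([a, b])
        # constants are translation fields: composition = accumulation
        np.testing.assert_allclose(out.vectors[:, 1:-1, 1:-1, 1:-1],
                                   acc.vectors[:, 1:-1, 1:-1, 1:-1],
                                   atol=1e-6)

    def test_agrees_with_accumulation_to_first_order(self):
        from morphcascade.phantom import DeformationSpec, make_smooth_field
        eps = 0.5
        a = make_smooth_field(DeformationSpec(size=16, max_disp=eps,
                                              smoothness_sigma=3.0, seed=1))
        b = make_smooth_field(DeformationSpec(size=16, max_disp=eps,
                                              smoothness_sigma=3.0, seed=2))
        comp = compose_fields([a, b]).vectors
        acc = accumulate_fields([a, b]).vectors
        assert np.abs(comp - acc).max() <= eps ** 2

    def test_generally_not_commutative(self):
        # a shears along axis 0, b translates along axis 1: orders differ
        shape = (8, 8, 8)
        shear = np.zeros((3,) + shape, dtype=np.float32)
        shear[0] = 0.5 * np.indices(shape)[1]
        a = DisplacementField(shear)
        b = constant_field(shape, (0, 2, 0))
        ab = compose_fields([a, b]).vectors
        ba = compose_fields([b, a]).vectors
        assert np.abs(ab - ba).max() > 0.5

    def test_shape_mismatch_rejected(self, smooth_field16):
        with pytest.raises(VolumeError):
            compose_fields([smooth_field16,
                            DisplacementField.zeros((8, 8, 8))])


class TestJacobian:
    def test_zero_field(self):
        report = jacobian_report(DisplacementField.zeros((6, 6, 6)))
        np.testing.assert_allclose(report.det_map, 1.0, atol=1e-12)
        assert report.neg_fraction == 0.0

    def test_uniform_expansion_determinant(self):
        # phi(x) = 0.1 x per axis -> det(I + grad phi) = 1.1^3 = 1.331
        shape = (8, 8, 8)
        idx = np.indices(shape, dtype=np.float64)
        field = DisplacementField(0.1 * idx)
        report = jacobian_report(field)
        np.testing.assert_allclose(report.det_map, 1.331, atol=1e-6)
        assert report.neg_fraction == 0.0

    def test_fold_detected_everywhere(self):
        shape = (8, 8, 8)
        v = np.zeros((3,) + shape)
        v[0] = -2.0 * np.indices(shape)[0]
        report = jacobian_report(DisplacementField(v))
        np.testing.assert_allclose(report.det_map, -1.0, atol=1e-6)
        assert report.neg_fraction == 100.0

    def test_grid_too_small(self):
        with pytest.raises(VolumeError):
            jacobian_report(DisplacementField.zeros((2, 4, 4)))


def test_field_nifti_round_trip(tmp_path, smooth_field16):
    path = tmp_path / "field.nii.gz"
    write_field(smooth_field16, path)
    back = read_field(path)
    np.testing.assert_allclose(back.vectors, smooth_field16.vectors,
                               atol=1e-6)
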