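import numpy as np
import pytest

from sctsynth.grid import Modality, VolumeGrid
from sctsynth.phantom import generate_phantom, sampling_map_world, warp_mr
from sctsynth.preprocess import (
    DegenerateInputError,
    EmptyForegroundError,
    NormalizationSpec,
    crop_or_pad_array,
    denormalize_ct,
    extract_body_mask,
    filter_slices,
    normalize_ct,
    normalize_mr,
    register_affine,
    resample_volume,
)


class TestResample:
    def test_identity_spacing_keeps_values(self, rng):
        vol = VolumeGrid(rng.normal(size=(4, 6, 6)), (2.0, 3.0, 3.0), modality=Modality.MR_AU)
        out = resample_volume(vol, (2.0, 3.0, 3.0))
        assert np.array_equal(out.values, vol.values)

    def test_constant_volume_preserved(self):
        vol = VolumeGrid(np.full((4, 8, 8), 7.0), (2.0, 2.0, 2.0), modality=Modality.MR_AU)
        out = resample_volume(vol, (1.0, 3.0, 1.5))
        # interior voxels (away from the out-of-field border) keep the constant
        assert np.allclose(out.values[:-1, :-1, :-1], 7.0)

    def test_linear_field_resampled_exactly(self):
        """Trilinear interpolation reproduces a plane to 1e-6 in the interior."""
        shape, spacing = (6, 8, 8), (2.0, 1.5, 1.5)
        zs = np.arange(shape[0]) * spacing[0]
        ys = np.arange(shape[1]) * spacing[1]
        xs = np.arange(shape[2]) * spacing[2]
        plane = (
            2.0 * zs[:, None, None] - 1.0 * ys[None, :, None] + 0.5 * xs[None, None, :] + 3.0
        )
        vol = VolumeGrid(plane, spacing, modality=Modality.MR_AU)
        target = (1.3, 1.1, 0.7)
        out = resample_volume(vol, target)
        zo = np.arange(out.shape[0]) * target[0]
        yo = np.arange(out.shape[1]) * target[1]
        xo = np.arange(out.shape[2]) * target[2]
        expect = 2.0 * zo[:, None, None] - 1.0 * yo[None, :, None] + 0.5 * xo[None, None, :] + 3.0
        interior = (
            (zo <= zs[-1])[:, None, None]
            & (yo <= ys[-1])[None, :, None]
            & (xo <= xs[-1])[None, None, :]
        )
        assert np.allclose(out.values[interior], expect[interior], atol=1e-6)

    def test_field_of_view_preserved(self):
        vol = VolumeGrid(np.zeros((10, 10, 10)), (2.0, 2.0, 2.0), modality=Modality.MR_AU)
        out = resample_volume(vol, (3.0, 3.0, 3.0))
        for a in range(3):
            assert abs(out.shape[a] * 3.0 - 20.0) <= 3.0

    def test_rejects_bad_spacing(self):
        vol = VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1), modality=Modality.MR_AU)
        with pytest.raises(ValueError):
            resample_volume(vol, (0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            resample_volume(vol, (1.0, 1.0, 1.0), interpolation="cubic")


class TestBodyMask:
    def test_phantom_couch_removed_and_body_recovered(self, zero_noise_case):
        body = extract_body_mask(zero_noise_case.ct)
        couch = zero_noise_case.labels.labels == 9
        assert not (body & couch).any()
        truth = zero_noise_case.body_label_mask()
        dsc = 2 * (body & truth).sum() / (body.sum() + truth.sum())
        assert dsc >= 0.98

    def test_all_air_raises(self):
        ct = VolumeGrid(np.full((4, 4, 4), -1000.0), (1, 1, 1))
        with pytest.raises(EmptyForegroundError):
            extract_body_mask(ct)

    def test_single_ellipsoid_exact(self):
        z, y, x = np.ogrid[-3:4, -5:6, -5:6]
        ellipsoid = (z / 3.0) ** 2 + (y / 5.0) ** 2 + (x / 5.0) ** 2 <= 1
        ct = VolumeGrid(np.where(ellipsoid, 40.0, -1000.0), (2, 2, 2))
        assert np.array_equal(extract_body_mask(ct), ellipsoid)


class TestNormalization:
    def test_ct_anchor_points(self):
        ct = VolumeGrid(np.array([[[-1024.0, 3071.0, 1023.5]]]), (1, 1, 1))
        out = normalize_ct(ct)
        assert np.allclose(out.values, [[[-1.0, 1.0, 0.0]]])

    def test_ct_round_trip_exact(self, rng):
        vals = rng.uniform(-1024, 3071, size=(3, 4, 4))
        ct = VolumeGrid(vals, (1, 1, 1))
        back = denormalize_ct(normalize_ct(ct))
        assert np.allclose(back.values, vals, atol=1e-9)

    def test_ct_out_of_range_clipped(self):
        ct = VolumeGrid(np.array([[[-1024.0]]]), (1, 1, 1))
        ct.values[...] = -2000.0  # bypass construction check to test clipping
        assert normalize_ct(ct).values.item() == -1.0

    def test_mr_definition_boundaries_explicit(self):
        # body voxels engineered to mean 10, sd 4
        body_vals = np.array([6.0, 14.0, 6.0, 14.0, 6.0, 14.0, 6.0, 14.0])
        vals = np.concatenate([body_vals, [10.0, 20.0, 30.0]])[None, None, :]
        mr = VolumeGrid(vals, (1, 1, 1), modality=Modality.MR_AU)
        body = np.zeros(vals.shape, bool)
        body[0, 0, :8] = True
        out = normalize_mr(mr, body).values[0, 0]
        mu, sd = 10.0, 4.0
        assert out[8] == pytest.approx(0.0)  # value at the body mean
        assert out[9] == pytest.approx(1.0)  # mu + 2.5 sd
        assert out[10] == pytest.approx(1.0)  # clipped beyond mu + 5 sd

    def test_mr_degenerate_sd_raises(self):
        mr = VolumeGrid(np.full((2, 2, 2), 5.0), (1, 1, 1), modality=Modality.MR_AU)
        with pytest.raises(DegenerateInputError):
            normalize_mr(mr, np.ones((2, 2, 2), bool))
        with pytest.raises(DegenerateInputError):
            normalize_mr(mr, np.zeros((2, 2, 2), bool))


class TestSliceFilter:
    def _mr(self, shape):
        return VolumeGrid(np.zeros(shape), (1, 1, 1), modality=Modality.MR_AU)

    def test_full_coverage_keeps_all(self):
        body = np.ones((3, 10, 10), bool)
        rep = filter_slices(self._mr(body.shape), body)
        assert rep.kept == [0, 1, 2]
        assert np.allclose(rep.coverage, 1.0)

    @pytest.mark.parametrize(
        "covered,expected_kept", [(90, False), (95, True), (94, False), (100, True)]
    )
    def test_five_percent_rule_boundary(self, covered, expected_kept):
        body = np.zeros((1, 10, 10), bool)
        body[0, :10, :10] = True  # 100 body voxels
        valid = np.zeros_like(body)
        valid[0].flat[:covered] = True
        rep = filter_slices(self._mr(body.shape), body, valid)
        assert (0 in rep.kept) is expected_kept
        assert rep.coverage[0] == pytest.approx(covered / 100)

    def test_slice_without_body_kept(self):
        body = np.zeros((2, 4, 4), bool)
        body[1] = True
        rep = filter_slices(self._mr(body.shape), body, np.ones_like(body))
        assert rep.kept == [0, 1]


class TestCropOrPad:
    def test_identity(self, rng):
        arr = rng.normal(size=(3, 8, 8))
        assert np.array_equal(crop_or_pad_array(arr, (8, 8)), arr)

    def test_crop_then_pad_restores_interior(self, rng):
        arr = rng.normal(size=(2, 12, 12))
        cropped = crop_or_pad_array(arr, (8, 8), "center")
        padded = crop_or_pad_array(cropped, (12, 12), "center", pad_value=0.0)
        assert np.array_equal(padded[:, 2:10, 2:10], arr[:, 2:10, 2:10])
        assert np.all(padded[:, :2, :] == 0.0)
        assert np.all(padded[:, :, 10:] == 0.0)

    def test_random_mode_seeded(self, rng):
        arr = rng.normal(size=(2, 12, 12))
        a = crop_or_pad_array(arr, (8, 8), "random", rng=np.random.default_rng(7))
        b = crop_or_pad_array(arr, (8, 8), "random", rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            crop_or_pad_array(np.zeros((2, 4, 4)), (0, 4))


class TestRegistration:
    def test_identity_recovered(self, bounded_spec):
        case = generate_phantom(bounded_spec, 2)
        body = extract_body_mask(case.ct)
        reg = register_affine(case.mr, case.ct, fixed_body=body)
        assert reg.converged
        assert np.all(np.abs(reg.translation_mm) < 0.5)
        assert np.all(np.abs(reg.rotation_deg) < 0.5)

    @pytest.mark.parametrize("shift", [(5.0, 0.0, 0.0), (0.0, 5.0, 0.0)])
    def test_known_translation_recovered_within_1mm(self, bounded_spec, shift):
        case = generate_phantom(bounded_spec, 2)
        body = extract_body_mask(case.ct)
        moved = warp_mr(case, translation_mm=shift)
        reg = register_affine(moved.mr, case.ct, fixed_body=body)
        # the registration reports the correcting shift, i.e. minus the motion
        assert np.all(np.abs(-reg.translation_mm - np.asarray(shift)) < 1.0)

    def test_elastic_residual_not_removed(self, bounded_spec):
        """Affine registration leaves the elastic component: the mean residual
        displacement stays of the order of (and below) the elastic amplitude."""
        from sctsynth.phantom import _smooth_displacement

        case = generate_phantom(bounded_spec.with_zero_noise(), 4)
        body = extract_body_mask(case.ct)
        amp = 3.0
        disp = _smooth_displacement(
            np.random.default_rng(5), case.mr.shape, case.mr.spacing, amp, 40.0
        )
        moved = warp_mr(case, translation_mm=(0.0, 3.0, -2.0), displacement=disp)
        reg = register_affine(moved.mr, case.ct, fixed_body=body)
        # residual map: apply the recovered correction, then the true motion
        corrected_pts = sampling_map_world(reg.affine, None, case.ct)
        from scipy import ndimage as ndi

        idx = np.stack(
            [
                (corrected_pts[a] - case.mr.origin[a]) / case.mr.spacing[a]
                for a in range(3)
            ]
        )
        true_pts = sampling_map_world(moved.true_affine, moved.true_displacement, case.mr)
        resampled_true = np.stack(
            [ndi.map_coordinates(true_pts[a], idx, order=1, mode="nearest") for a in range(3)]
        )
        zs, ys, xs = case.ct.world_coords()
        identity = np.stack(np.meshgrid(zs, ys, xs, indexing="ij"))
        residual = np.sqrt(((resampled_true - identity) ** 2).sum(axis=0))
        assert residual[body].mean() <= amp
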