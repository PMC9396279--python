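"""Preprocessing geometry: crop, overlapping patches, stitching, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusionsynth.mri_io import (GeometryError, PatchRecord, Volume,
                                central_crop, extract_patches, load_volume,
                                patch_offsets, save_volume, scale_intensity,
                                slice_triplets, stitch_patches, stitch_volume,
                                unscale_intensity)


def random_volume(shape, seed=0):
    return Volume(np.random.default_rng(seed).normal(size=shape),
                  modality="m", case_id="c")


class TestCentralCrop:
    def test_standard_brain_crop_window(self):
        vol = random_volume((2, 240, 240))
        out = central_crop(vol, (160, 180))
        np.testing.assert_array_equal(out.data, vol.data[:, 40:200, 30:210])

    def test_identity_when_crop_equals_shape(self):
        vol = random_volume((2, 32, 48))
        np.testing.assert_array_equal(central_crop(vol, (32, 48)).data, vol.data)

    def test_constant_slice_stays_constant(self):
        vol = Volume(np.full((1, 20, 20), 3.5))
        assert (central_crop(vol, (10, 12)).data == 3.5).all()

    def test_odd_margin_rounds_leading_margin_down(self):
        vol = random_volume((1, 7, 7))
        out = central_crop(vol, (4, 4))
        np.testing.assert_array_equal(out.data, vol.data[:, 1:5, 1:5])

    def test_too_large_crop_raises(self):
        with pytest.raises(GeometryError):
            central_crop(random_volume((1, 10, 10)), (11, 10))


class TestPatches:
    def test_four_corner_offsets_for_brain_geometry(self):
        assert patch_offsets((160, 180), (128, 128)) == [
            (0, 0), (0, 52), (32, 0), (32, 52)]

    def test_patches_cover_plane_and_corners(self):
        vol = random_volume((1, 160, 180))
        pats = extract_patches(vol, (128, 128))
        assert len(pats) == 4
        cover = np.zeros((160, 180))
        for p in pats:
            r, c = p.crop_offset
            cover[r:r + 128, c:c + 128] += 1
        assert (cover >= 1).all()
        corner = next(p for p in pats if p.crop_offset == (32, 52))
        np.testing.assert_array_equal(corner.pixels, vol.data[0, 32:, 52:])

    def test_degenerate_same_size_plane_gives_single_patch(self):
        vol = random_volume((2, 128, 128))
        pats = extract_patches(vol, (128, 128))
        assert len(pats) == 2          # one per slice, duplicates removed

    def test_round_trip_is_exact(self):
        vol = random_volume((1, 160, 180), seed=3)
        pats = extract_patches(vol, (128, 128))
        rec = stitch_patches(pats, (160, 180))
        assert np.abs(rec - vol.data[0]).max() == 0.0

    def test_overlap_averages(self):
        a = PatchRecord(np.zeros((4, 4)), crop_offset=(0, 0))
        b = PatchRecord(np.ones((4, 4)), crop_offset=(0, 2))
        out = stitch_patches([a, b], (4, 6))
        np.testing.assert_array_equal(out[:, 2:4], np.full((4, 2), 0.5))

    def test_incomplete_coverage_raises_with_location(self):
        a = PatchRecord(np.zeros((4, 4)), crop_offset=(0, 0))
        with pytest.raises(GeometryError, match="uncovered"):
            stitch_patches([a], (8, 8))

    @settings(max_examples=25, deadline=None)
    @given(h=st.integers(10, 40), w=st.integers(10, 40),
           dh=st.integers(0, 20), dw=st.integers(0, 20),
           seed=st.integers(0, 100))
    def test_round_trip_identity_fuzzed(self, h, w, dh, dw, seed):
        # the two corner-anchored offsets cover the plane iff patch >= half
        ph, pw = h - min(dh, h // 2), w - min(dw, w // 2)
        vol = random_volume((1, h, w), seed=seed)
        rec = stitch_patches(extract_patches(vol, (ph, pw)), (h, w))
        assert np.abs(rec - vol.data[0]).max() < 1e-12

    def test_stitch_volume_reassembles_all_slices(self):
        vol = random_volume((3, 20, 24), seed=8)
        pats = extract_patches(vol, (16, 16))
        out = stitch_volume(pats, vol.shape)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)


class TestScaling:
    def test_symmetric_values_map_linearly(self):
        vol = Volume(np.array([[[-2.0, 0.0, 2.0]]]))
        out, _ = scale_intensity(vol)
        np.testing.assert_array_equal(out.data, [[[-1.0, 0.0, 1.0]]])

    def test_constant_volume_maps_to_zeros(self):
        out, params = scale_intensity(Volume(np.full((1, 2, 2), 7.0)))
        assert (out.data == 0.0).all()
        assert (unscale_intensity(out.data, params) == 7.0).all()

    def test_round_trip_within_float_tolerance(self):
        vol = random_volume((2, 8, 8), seed=2)
        out, params = scale_intensity(vol)
        assert out.data.min() == -1.0 and out.data.max() == 1.0
        np.testing.assert_allclose(unscale_intensity(out.data, params),
                                   vol.data, atol=1e-12)

    def test_non_finite_values_raise(self):
        with pytest.raises(ValueError):
            scale_intensity(Volume(np.array([[[np.nan, 1.0]]])))

    def test_per_slice_mode_scales_each_slice_independently(self):
        vol = random_volume((3, 6, 6), seed=4)
        out, params = scale_intensity(vol, mode="slice")
        assert len(params) == 3
        for k, p in enumerate(params):
            assert out.data[k].min() == -1.0 and out.data[k].max() == 1.0
            np.testing.assert_allclose(unscale_intensity(out.data[k], p),
                                       vol.data[k], atol=1e-12)

    def test_fixed_range_mode_uses_supplied_bounds(self):
        vol = Volume(np.array([[[0.0, 5.0, 10.0]]]))
        out, p = scale_intensity(vol, mode="fixed", fixed_range=(0.0, 10.0))
        np.testing.assert_array_equal(out.data, [[[-1.0, 0.0, 1.0]]])
        with pytest.raises(ValueError):
            scale_intensity(vol, mode="fixed")
        with pytest.raises(ValueError):
            scale_intensity(vol, mode="no_such_mode")


class TestTriplets:
    def test_edge_replication_and_labels(self):
        vol = random_volume((5, 4, 4), seed=1)
        trips = slice_triplets(vol)
        assert [t.slice_index for t in trips] == [0, 1, 2, 3, 4]
        np.testing.assert_array_equal(trips[0].pixels,
                                      vol.data[[0, 0, 1]])
        np.testing.assert_array_equal(trips[-1].pixels,
                                      vol.data[[3, 4, 4]])

    def test_middle_stack_of_depth3_is_whole_volume(self):
        vol = random_volume((3, 4, 4))
        np.testing.assert_array_equal(slice_triplets(vol)[1].pixels, vol.data)

    def test_depth_below_three_raises(self):
        with pytest.raises(GeometryError):
            slice_triplets(random_volume((2, 4, 4)))


def test_nifti_round_trip(tmp_path):
    vol = Volume(np.random.default_rng(0).random((4, 6, 5)).astype(np.float32),
                 modality="source1", case_id="c1")
    path = tmp_path / "vol.nii.gz"
    save_volume(vol, path)
    back = load_volume(path, modality="source1", case_id="c1")
    np.testing.assert_allclose(back.data, vol.data, atol=1e-6)
    np.testing.assert_array_equal(back.affine, vol.affine)
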