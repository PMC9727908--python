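"""Preprocessing chain: crop, orient, mask, split, detrend, normalize."""

import dataclasses

import numpy as np
import pytest

from phantomqc import preprocess as pp
from phantomqc.errors import (ConstantPatchError, InvalidArgumentError,
                              NoPhantomDetectedError, WaxNotFoundError)
from phantomqc.phantom_synth import (DEFAULT_LAYOUT, PhantomImage,
                                     PhantomLayout, generate_phantom)


class TestExtractPhantom:
    def test_crop_matches_generator_placement(self, phantom_pair):
        image, gt = phantom_pair
        _, bounds = pp.extract_phantom(image)
        assert all(abs(a - b) <= 2 for a, b in zip(bounds, gt.phantom_bbox_px))

    def test_uniform_image_rejected(self):
        flat = PhantomImage(pixels=np.full((200, 200), 500.0), pixel_size_um=100.0)
        with pytest.raises(NoPhantomDetectedError):
            pp.extract_phantom(flat)

    def test_phantom_flush_to_border_still_cropped(self, profile):
        layout = dataclasses.replace(DEFAULT_LAYOUT, phantom_origin_mm=(0.0, 10.0),
                                     wax_origin_mm=(15.0, 20.0))
        image, gt = generate_phantom(profile, 1.0, seed=2, layout=layout)
        _, bounds = pp.extract_phantom(image)
        assert bounds[0] == 0
        assert all(abs(a - b) <= 2 for a, b in zip(bounds, gt.phantom_bbox_px))


class TestExtractWax:
    def test_wax_bounds_close_to_ground_truth(self, phantom_pair):
        image, gt = phantom_pair
        crop, pbounds = pp.extract_phantom(image)
        wax = pp.extract_wax_area(crop)
        r0, c0, r1, c1 = wax.crop_bounds
        found = (r0 + pbounds[0], c0 + pbounds[1], r1 + pbounds[0], c1 + pbounds[1])
        area = (r1 - r0) * (c1 - c0)
        er0, ec0, er1, ec1 = gt.wax_bbox_px
        expected_area = (er1 - er0) * (ec1 - ec0)
        assert area == pytest.approx(expected_area, rel=0.01)
        assert all(abs(a - b) <= 8 for a, b in zip(found, gt.wax_bbox_px))

    def test_precropped_wax_returned_unchanged(self, wax):
        again = pp.extract_wax_area(wax.pixels)
        np.testing.assert_array_equal(again.pixels, wax.pixels)

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(WaxNotFoundError):
            pp.extract_wax_area(rng.normal(0.0, 1.0, (400, 400)))

    def test_crop_area_stable_over_noisy_renders(self, profile):
        """Repeated acquisitions of one phantom crop to nearly the same
        wax area (>= 95% of crops within 1% of the mean area)."""
        areas = []
        for seed in range(20):
            image, _ = generate_phantom(profile, 1.0, seed=200 + seed)
            crop, _ = pp.extract_phantom(image)
            w = pp.extract_wax_area(crop)
            r0, c0, r1, c1 = w.crop_bounds
            areas.append((r1 - r0) * (c1 - c0))
        areas = np.asarray(areas, dtype=float)
        within = np.abs(areas / areas.mean() - 1.0) <= 0.01
        assert within.mean() >= 0.95


class TestOrientation:
    def test_180_rotation_recovered(self, wax):
        flipped = dataclasses.replace(wax, pixels=np.rot90(wax.pixels, 2),
                                      rotation_applied=0)
        out = pp.orient_by_largest_mass(flipped)
        assert out.rotation_applied == 180
        np.testing.assert_array_equal(out.pixels, wax.pixels)

    def test_correct_orientation_is_identity(self, wax):
        out = pp.orient_by_largest_mass(wax)
        assert out.rotation_applied == 0
        np.testing.assert_array_equal(out.pixels, wax.pixels)

    def test_orientation_idempotent(self, wax):
        once = pp.orient_by_largest_mass(wax)
        twice = pp.orient_by_largest_mass(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_low_dose_orientation_matches_clean_decision(self, profile):
        for k in (1, 2, 3):
            clean, _ = generate_phantom(profile, float("inf"), seed=8)
            noisy, _ = generate_phantom(profile, 0.5, seed=8)
            cw = pp.extract_wax_area(pp.extract_phantom(clean)[0])
            nw = pp.extract_wax_area(pp.extract_phantom(noisy)[0])
            cw = dataclasses.replace(cw, pixels=np.rot90(cw.pixels, k))
            nw = dataclasses.replace(nw, pixels=np.rot90(nw.pixels, k))
            assert (pp.orient_by_largest_mass(cw).rotation_applied
                    == pp.orient_by_largest_mass(nw).rotation_applied)

    def test_featureless_input_flagged_ambiguous(self):
        rng = np.random.default_rng(1)
        flat = pp.WaxImage(pixels=rng.normal(1000.0, 1.0, (300, 300)),
                           crop_bounds=(0, 0, 300, 300))
        out = pp.orient_by_largest_mass(flat)
        assert "orientation-ambiguous" in out.warnings
        np.testing.assert_array_equal(out.pixels, flat.pixels)


class TestMaskName:
    def test_masked_region_blends_with_surrounding_wax(self, wax):
        config = pp.PreprocessConfig()
        out = pp.mask_name_region(wax, config, seed=5)
        (r0, c0, r1, c1) = out.masked_regions[-1]
        region = out.pixels[r0:r1, c0:c1]
        pad = 30
        frame = out.pixels[max(0, r0 - pad):r1 + pad, max(0, c0 - pad):c1 + pad]
        assert region.mean() == pytest.approx(frame.mean(), rel=0.05)
        # the dark burned-in text is gone
        assert region.min() > wax.pixels[r0:r1, c0:c1].min() + 500

    def test_empty_region_is_identity(self, wax):
        config = pp.PreprocessConfig(name_mask_region=(0.0, 0.0, 0.0, 0.0))
        out = pp.mask_name_region(wax, config, seed=5)
        np.testing.assert_array_equal(out.pixels, wax.pixels)
        assert out.masked_regions == []

    def test_fill_reproducible_under_seed(self, wax):
        a = pp.mask_name_region(wax, seed=9)
        b = pp.mask_name_region(wax, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestSplitSubimages:
    def test_sixteen_patches_each_containing_its_target(self, wax, layout):
        patches = pp.split_subimages(wax)
        assert [pos for _, pos in patches] == list(range(1, 17))
        h, w = wax.pixels.shape
        for patch, pos in patches:
            fr, fc, fs = pp.PreprocessConfig().target_squares[pos - 1]
            cr, cc = layout.cell_center(pos)
            # the configured centre falls inside the extracted square
            r0 = int(round(fr * h))
            c0 = int(round(fc * w))
            assert r0 <= cr * h <= r0 + patch.shape[0]
            assert c0 <= cc * w <= c0 + patch.shape[1]

    def test_overlapping_squares_permitted(self, wax):
        config = pp.PreprocessConfig()
        big = [(fr - 0.05, fc - 0.05, fs + 0.10)
               for fr, fc, fs in config.target_squares]
        patches = pp.split_subimages(wax, pp.PreprocessConfig(target_squares=big))
        assert len(patches) == 16

    def test_cr_patches_twice_as_wide_as_ffdm(self, profiles):
        ffdm = profiles[0]  # 100 um
        cr = profiles[-1]  # 50 um
        assert ffdm.pixel_size_um == 100.0 and cr.pixel_size_um == 50.0
        widths = {}
        for prof in (ffdm, cr):
            image, _ = generate_phantom(prof, 1.0, seed=1)
            waxim = pp.extract_wax_area(pp.extract_phantom(image)[0])
            patch, _ = pp.split_subimages(waxim)[0]
            widths[prof.pixel_size_um] = patch.shape[0]
        assert widths[50.0] == pytest.approx(2 * widths[100.0], rel=0.03)


class TestDetrend:
    def test_exact_fit_of_matching_polynomial_orders(self):
        yy, xx = np.mgrid[0:64, 0:64] / 63.0
        plane = 5.0 + 2.0 * yy - 3.0 * xx
        resid = pp.detrend_background(plane, position=7)
        assert np.abs(resid).max() < 1e-9 * np.abs(plane).max()
        quintic = ((yy - 0.3) ** 5 + (xx - 0.6) ** 3 * yy ** 2
                   + 4.0 * xx * yy - 1.0)
        resid5 = pp.detrend_background(quintic, position=1)
        assert np.abs(resid5).max() < 1e-9

    def test_disk_amplitude_preserved_over_plane(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        plane = 0.05 * yy - 0.02 * xx + 40.0
        disk = 100.0 * (np.hypot(yy - 64, xx - 64) <= 20)
        out = pp.detrend_background(plane + disk, position=12)
        amp = out[64, 64] - np.median(out[disk == 0])
        assert amp == pytest.approx(100.0, rel=0.02)

    def test_nonfinite_patch_rejected(self):
        bad = np.ones((32, 32))
        bad[3, 3] = np.nan
        with pytest.raises(InvalidArgumentError):
            pp.detrend_background(bad, position=1)


class TestToModelInput:
    def test_output_contract(self):
        rng = np.random.default_rng(0)
        sub = pp.to_model_input(rng.normal(0, 1, (256, 256)), position=3)
        assert sub.pixels.shape == (128, 128)
        assert sub.pixels.dtype == np.float64
        assert sub.pixels.min() == 0.0 and sub.pixels.max() == 1.0

    def test_peak_position_maps_through_resize(self):
        patch = np.zeros((190, 190))
        patch[60, 120] = 1.0
        from scipy import ndimage

        patch = ndimage.gaussian_filter(patch, 3.0)
        sub = pp.to_model_input(patch, position=1)
        peak = np.unravel_index(np.argmax(sub.pixels), sub.pixels.shape)
        assert abs(peak[0] - 60 * 128 / 190) <= 1
        assert abs(peak[1] - 120 * 128 / 190) <= 1

    def test_constant_patch_rejected(self):
        with pytest.raises(ConstantPatchError):
            pp.to_model_input(np.full((64, 64), 7.0), position=1)


class TestEndToEnd:
    def test_sixteen_normalized_subimages_per_image(self, subimages):
        assert len(subimages) == 16
        assert [s.position for s in subimages] == list(range(1, 17))
        for s in subimages:
            assert s.pixels.shape == (128, 128)
            assert s.pixels.min() >= 0.0 and s.pixels.max() <= 1.0
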