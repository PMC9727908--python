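"""Noise augmentation: templates, mosaics, degradation, averaging, rotation."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from phantomqc import augment as ag
from phantomqc import preprocess as pp
from phantomqc.errors import (AlignmentFailedError, DegenerateTemplateError,
                              InvalidArgumentError)
from phantomqc.phantom_synth import (DEFAULT_LAYOUT, PhantomImage,
                                     generate_phantom)


def _template_region(wax):
    """A target-free strip left of the target grid."""
    h, w = wax.pixels.shape
    return (int(0.30 * h), 0, int(0.90 * h), int(0.05 * w))


@pytest.fixture(scope="module")
def template(wax):
    return ag.build_noise_template(wax, _template_region(wax),
                                   pp.PreprocessConfig().target_squares,
                                   device_id="dev01")


class TestNoiseTemplate:
    def test_template_dims_equal_region(self, wax, template):
        r0, c0, r1, c1 = _template_region(wax)
        assert template.pixels.shape == (r1 - r0, c1 - c0)

    def test_region_overlapping_target_square_rejected(self, wax):
        h, w = wax.pixels.shape
        fr, fc, fs = pp.PreprocessConfig().target_squares[2]  # f3 square
        bad = (int(fr * h), int(fc * w), int(fr * h) + 40, int(fc * w) + 40)
        with pytest.raises(InvalidArgumentError):
            ag.build_noise_template(wax, bad, pp.PreprocessConfig().target_squares)

    def test_template_variance_matches_generator_noise(self, profile):
        """On a texture-free background the template variance is the
        generator's noise variance."""
        layout = dataclasses.replace(DEFAULT_LAYOUT, texture_amplitude=0.0,
                                     gradient_amplitude=0.0)
        image, gt = generate_phantom(profile, 1.0, seed=21, layout=layout)
        waxim = pp.extract_wax_area(pp.extract_phantom(image)[0])
        tem = ag.build_noise_template(waxim, _template_region(waxim),
                                      pp.PreprocessConfig().target_squares)
        assert tem.pixels.var() == pytest.approx(gt.noise_sigma ** 2, rel=0.10)


class TestPatchMosaic:
    def test_single_tile_mosaic_is_a_template_patch(self, template):
        out = ag.sample_patch_mosaic(template, (10, 10), seed=0)
        ps = template.patch_size
        th, tw = template.pixels.shape
        matches = any(
            np.array_equal(out, template.pixels[i * ps:(i + 1) * ps,
                                                j * ps:(j + 1) * ps])
            for i in range(th // ps) for j in range(tw // ps))
        assert matches

    def test_mosaic_deterministic_under_seed(self, template):
        a = ag.sample_patch_mosaic(template, (64, 97), seed=5)
        b = ag.sample_patch_mosaic(template, (64, 97), seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (64, 97)

    def test_large_mosaic_preserves_template_variance(self):
        rng = np.random.default_rng(3)
        tem = ag.NoiseTemplate(pixels=rng.normal(0.0, 1.0, (100, 100)))
        mosaic = ag.sample_patch_mosaic(tem, (400, 400), seed=1)
        assert mosaic.var() == pytest.approx(tem.pixels.var(), rel=0.05)

    def test_invalid_shape_rejected(self, template):
        with pytest.raises(InvalidArgumentError):
            ag.sample_patch_mosaic(template, (0, 10))


class TestDegrade:
    def test_zero_weight_is_identity(self, phantom_pair, template):
        image, _ = phantom_pair
        out = ag.degrade_image(image, template, 0.0, seed=1)
        np.testing.assert_array_equal(out.pixels, image.pixels)

    def test_constant_image_and_template_mean_preserved(self):
        image = PhantomImage(pixels=np.full((50, 50), 100.0), pixel_size_um=100.0)
        tem = ag.NoiseTemplate(pixels=np.full((20, 20), 50.0))
        out = ag.degrade_image(image, tem, 0.5, seed=0)
        np.testing.assert_allclose(out.pixels, 100.0)

    def test_wax_mean_preserved_within_one_percent(self, phantom_pair, template):
        image, gt = phantom_pair
        r0, c0, r1, c1 = gt.wax_bbox_px
        for w in (0.3, 0.55, 0.8):
            out = ag.degrade_image(image, template, w, seed=2,
                                   wax_bounds=(r0, c0, r1, c1))
            assert out.pixels[r0:r1, c0:c1].mean() == pytest.approx(
                image.pixels[r0:r1, c0:c1].mean(), rel=0.01)

    def test_noise_increases_monotonically_with_weight(self, profile, template):
        """Mixing attenuates target contrast by (1 - w), so the noise that
        matters for conspicuity is the residual relative to the retained
        signal; it must grow strictly with the mixing weight."""
        clean, gt = generate_phantom(profile, 1.0, seed=30, with_noise=False)
        noisy, _ = generate_phantom(profile, 1.0, seed=30)
        r0, c0, r1, c1 = gt.wax_bbox_px
        variances = []
        for w in (0.3, 0.5, 0.8):
            out = ag.degrade_image(noisy, template, w, seed=3,
                                   wax_bounds=(r0, c0, r1, c1))
            resid = (out.pixels - (1 - w) * clean.pixels)[r0:r1, c0:c1]
            variances.append(resid.var() / (1 - w) ** 2)
        assert variances == sorted(variances)
        assert variances[0] < variances[-1] / 2

    def test_zero_mean_template_rejected(self, phantom_pair):
        image, _ = phantom_pair
        tem = ag.NoiseTemplate(pixels=np.zeros((20, 20)))
        with pytest.raises(DegenerateTemplateError):
            ag.degrade_image(image, tem, 0.5)


class TestCampaignCounts:
    def test_default_plan_yields_110_degraded_images(self, template):
        images = [PhantomImage(pixels=np.full((40, 40), 100.0) + i,
                               pixel_size_um=100.0) for i in range(3)]
        plan = ag.AugmentPlan(seed=4)
        out = ag.generate_degraded_set(images, template, plan)
        assert len(out) == 110
        weights = sorted({w for _, w in out})
        assert weights == [round(0.30 + 0.05 * i, 2) for i in range(11)]

    def test_custom_weight_plan_counts(self, template):
        images = [PhantomImage(pixels=np.full((40, 40), 100.0),
                               pixel_size_um=100.0)]
        plan = ag.AugmentPlan(mixing_weights=(0.3, 0.8), images_per_weight=10)
        assert len(ag.generate_degraded_set(images, template, plan)) == 20
        plan1 = ag.AugmentPlan(mixing_weights=(0.5,), images_per_weight=1)
        assert len(ag.generate_degraded_set(images, template, plan1)) == 1

    def test_default_plan_yields_120_averaged_images(self):
        rng = np.random.default_rng(0)
        srcs = [pp.WaxImage(pixels=rng.normal(100, 1, (32, 32)),
                            crop_bounds=(0, 0, 32, 32)) for _ in range(6)]
        out = ag.generate_averaged_set(srcs, ag.AugmentPlan(seed=1))
        assert len(out) == 120
        assert sorted({lvl for _, lvl in out}) == [2, 3, 4, 8]

    def test_empty_source_list_rejected(self, template):
        with pytest.raises(InvalidArgumentError):
            ag.generate_degraded_set([], template, ag.AugmentPlan())


class TestAlignment:
    LANDMARKS = list(ag.DEFAULT_ALIGNMENT_LANDMARKS)

    def test_small_rotation_recovered_on_grid(self, wax):
        moved = dataclasses.replace(
            wax, pixels=ndimage.rotate(wax.pixels, 0.25, reshape=False,
                                       order=1, mode="nearest"))
        angle, aligned = ag.align_by_specks(wax, moved, self.LANDMARKS)
        assert angle == pytest.approx(-0.25, abs=0.0501)
        assert abs(round(angle / 0.05) * 0.05 - angle) < 1e-9  # on the grid

    def test_identity_pair_gives_zero_angle(self, wax):
        angle, aligned = ag.align_by_specks(wax, wax, self.LANDMARKS)
        assert angle == 0.0
        np.testing.assert_allclose(aligned.pixels, wax.pixels)

    def test_pure_noise_pair_fails(self, wax):
        rng = np.random.default_rng(7)
        noise = dataclasses.replace(wax, pixels=rng.normal(0, 1, wax.pixels.shape))
        with pytest.raises(AlignmentFailedError):
            ag.align_by_specks(wax, noise, self.LANDMARKS)


class TestAveraging:
    def test_average_of_copies_is_identity(self, wax):
        out = ag.average_images([wax, wax, wax])
        np.testing.assert_allclose(out.pixels, wax.pixels)

    @pytest.mark.parametrize("n", [2, 4])
    def test_noise_variance_law(self, profile, n):
        clean, gt = generate_phantom(profile, 1.0, seed=50, with_noise=False)
        r0, c0, r1, c1 = gt.wax_bbox_px
        renders = []
        for s in range(n):
            noisy, _ = generate_phantom(profile, 1.0, seed=500 + s)
            renders.append(pp.WaxImage(pixels=noisy.pixels,
                                       crop_bounds=(0, 0, *noisy.pixels.shape)))
        avg = ag.average_images(renders)
        resid = (avg.pixels - clean.pixels)[r0:r1, c0:c1]
        expected = gt.noise_sigma ** 2 / n
        assert 0.8 * expected <= resid.var() <= 1.2 * expected

    def test_shape_mismatch_rejected(self, wax):
        small = pp.WaxImage(pixels=np.zeros((10, 10)), crop_bounds=(0, 0, 10, 10))
        with pytest.raises(InvalidArgumentError):
            ag.average_images([wax, small])


class TestRotationAugment:
    def test_angle_reproducible_under_seed(self, subimages):
        a = ag.rotation_augment(subimages[0], seed=3)
        b = ag.rotation_augment(subimages[0], seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.position == subimages[0].position

    def test_output_stays_in_unit_range(self, subimages):
        for seed in range(5):
            out = ag.rotation_augment(subimages[seed], seed=seed)
            assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
            assert out.pixels.shape == subimages[seed].pixels.shape

    def test_bright_spot_moves_along_expected_arc(self):
        img = np.zeros((128, 128))
        img[30, 96] = 1.0
        img = ndimage.gaussian_filter(img, 2.0)
        img /= img.max()
        sub = pp.SubImage(pixels=img, position=1)
        # seed chosen so the drawn angle is close to the +-3 degree edge
        rng = np.random.default_rng(12345)
        angle = float(rng.uniform(-3, 3))
        out = ag.rotation_augment(sub, seed=12345)
        peak = np.unravel_index(np.argmax(out.pixels), out.pixels.shape)
        c = (128 - 1) / 2.0
        t = np.deg2rad(angle)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        expected = rot @ (np.array([30.0, 96.0]) - c) + c
        assert abs(peak[0] - expected[0]) <= 1.5
        assert abs(peak[1] - expected[1]) <= 1.5
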