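"""Block-dataset construction: the 4/5 rules against brute force,
center-symmetric negative sampling, rotation augmentation and
normalization."""

import numpy as np
import pytest

from amcl import phantom, preprocess
from amcl.preprocess import HALF_HI, HALF_LO


def _image(pixels, mask=None):
    pixels = np.asarray(pixels, dtype=float)
    brain = np.ones_like(pixels, dtype=bool) if mask is None else mask
    return phantom.BrainImage(pixels, brain, "P1", "P1_1", "positive")


class TestResize:
    def test_identity_when_already_on_grid(self, rng):
        img = _image(rng.normal(size=(256, 256)))
        out = preprocess.resize_to_grid(img, 256)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = _image(np.full((100, 100), 3.7))
        out = preprocess.resize_to_grid(img, 256)
        np.testing.assert_allclose(out.pixels, 3.7)

    def test_ramp_matches_direct_bilinear_formula(self):
        """skimage's bilinear resample of a 128→256 linear ramp equals
        the interpolation formula x_src = (i+0.5)·scale − 0.5 applied to
        a linear function (frozen from the formula, probed at 4 rows)."""
        ramp = np.tile(np.arange(128, dtype=float)[:, None], (1, 128))
        out = preprocess.resize_to_grid(_image(ramp), 256)
        for i in (10, 100, 200, 250):
            x_src = np.clip((i + 0.5) * 128 / 256 - 0.5, 0, 127)
            assert out.pixels[i, 64] == pytest.approx(x_src, abs=1e-9)

    def test_small_target_rejected(self):
        with pytest.raises(ValueError):
            preprocess.resize_to_grid(_image(np.zeros((64, 64))), 16)

    def test_masks_resampled_nearest_and_binary(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 40:60] = True
        img = _image(np.ones((100, 100)))
        out, les = preprocess.resize_to_grid(img, 256, phantom.LesionMask(mask))
        assert les.mask.dtype == bool
        scale = (256 / 100) ** 2
        assert scale * mask.sum() * 0.8 < les.mask.sum() < scale * mask.sum() * 1.2


class TestZscore:
    def test_mean_zero_variance_one_inside_mask(self, rng):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 10:40] = True
        img = _image(rng.normal(2.0, 3.0, (50, 50)), mask)
        out = preprocess.zscore_normalize(img)
        assert out.pixels[mask].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.pixels[mask].var() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.pixels[~mask] == 0)

    def test_affine_invariance(self, rng):
        pix = rng.normal(size=(40, 40))
        a = preprocess.zscore_normalize(_image(pix))
        b = preprocess.zscore_normalize(_image(2.5 * pix - 7.0))
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-9)

    def test_two_pixel_mask_gives_plus_minus_one(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[0, 1] = True
        pix = np.zeros((4, 4))
        pix[0, 0], pix[0, 1] = 1.0, 3.0
        out = preprocess.zscore_normalize(_image(pix, mask))
        assert out.pixels[0, 0] == pytest.approx(-1.0)  # population SD = 1
        assert out.pixels[0, 1] == pytest.approx(+1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess.zscore_normalize(_image(np.ones((30, 30))))


class TestLesionBlockRule:
    def test_full_window_lesion_true(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:48, 20:48] = True  # a full 28×28 lesion square
        assert preprocess.is_lesion_block((33, 33), phantom.LesionMask(mask))

    def test_small_lesion_captured_by_total_rule(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 30:40] = True  # 10 lesion pixels, all inside the window
        assert preprocess.is_lesion_block((30, 34), phantom.LesionMask(mask))

    def test_partial_coverage_of_large_lesion_false(self):
        # 600 of 2000 lesion pixels in the window: 600 ≤ 627.2 and < 1600
        mask = np.zeros((128, 128), dtype=bool)
        mask[50:90, 30:80] = True
        assert mask.sum() == 2000
        # window centered at (78, 69) spans rows 65..92, cols 56..83:
        # overlap with the lesion is 25 rows × 24 cols = 600 pixels
        center = (78, 69)
        rows = np.arange(center[0] - 13, center[0] + 15)
        cols = np.arange(center[1] - 13, center[1] + 15)
        n_in = mask[np.ix_(rows, cols)].sum()
        assert n_in == 600
        assert n_in <= 0.8 * 784 and n_in < 0.8 * 2000
        assert not preprocess.is_lesion_block(center, phantom.LesionMask(mask))

    def test_out_of_bounds_center_rejected(self):
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError):
            preprocess.is_lesion_block((5, 30), mask)


class TestExtractPositive:
    def test_single_isolated_pixel_gives_one_block(self, rng):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 31] = True
        img = _image(rng.normal(size=(64, 64)))
        blocks = preprocess.extract_positive_blocks(img, phantom.LesionMask(mask))
        assert len(blocks) == 1
        assert blocks[0].center == (30, 31) and blocks[0].label == 1

    def test_empty_mask_gives_empty_list(self, rng):
        img = _image(rng.normal(size=(64, 64)))
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        assert preprocess.extract_positive_blocks(img, mask) == []

    def test_matches_bruteforce_enumeration(self, rng):
        """Every center kept by the vectorized extraction passes the
        explicit rule, and vice versa, on a random toy lesion."""
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 30) ** 2 + (xx - 26) ** 2 <= 150] = True
        img = _image(rng.normal(size=(64, 64)))
        lesion = phantom.LesionMask(mask)
        fast = {b.center for b in preprocess.extract_positive_blocks(img, lesion)}
        brute = set()
        for r, c in zip(*np.nonzero(mask)):
            if HALF_LO <= r <= 63 - HALF_HI and HALF_LO <= c <= 63 - HALF_HI:
                if preprocess.is_lesion_block((r, c), lesion):
                    brute.add((int(r), int(c)))
        assert fast == brute and brute

    def test_block_pixels_are_the_window(self, rng):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 30] = True
        img = _image(rng.normal(size=(64, 64)))
        b = preprocess.extract_positive_blocks(img, phantom.LesionMask(mask))[0]
        np.testing.assert_array_equal(
            b.pixels, img.pixels[30 - HALF_LO:30 + HALF_HI + 1,
                                 30 - HALF_LO:30 + HALF_HI + 1])


class TestExtractNegative:
    def test_lesionfree_image_yields_requested_blocks(self, rng):
        img = _image(rng.normal(size=(64, 64)))
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        blocks, short = preprocess.extract_negative_blocks(img, mask, 3, rng=rng)
        assert len(blocks) == 3 and not short
        assert all(b.label == 0 for b in blocks)

    def test_windows_and_reflections_are_lesion_free(self, rng):
        img, les = phantom.make_phantom(phantom.PhantomParams(seed=9))
        blocks, _ = preprocess.extract_negative_blocks(img, les, 60, rng=rng)
        h, w = les.mask.shape
        assert blocks
        for b in blocks:
            r, c = b.center
            win = les.mask[r - HALF_LO:r + HALF_HI + 1,
                           c - HALF_LO:c + HALF_HI + 1]
            assert win.sum() == 0
            # brute-force point reflection r' = H−1−r of every window pixel
            rows = np.arange(r - HALF_LO, r + HALF_HI + 1)
            cols = np.arange(c - HALF_LO, c + HALF_HI + 1)
            refl = les.mask[np.ix_((h - 1) - rows, (w - 1) - cols)]
            assert refl.sum() == 0

    def test_shortfall_flagged(self, rng):
        img = _image(np.ones((64, 64)) + rng.normal(size=(64, 64)) * 0.1)
        mask = np.zeros((64, 64), dtype=bool)
        mask[29:36, 29:36] = True  # central lesion blocks most reflections
        blocks, short = preprocess.extract_negative_blocks(
            img, phantom.LesionMask(mask), 10 ** 5, rng=rng)
        assert short and len(blocks) < 10 ** 5


class TestRotations:
    def test_default_step_gives_15_pairs_with_identity(self, rng):
        img = _image(rng.normal(size=(64, 64)))
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        pairs = preprocess.augment_rotations(img, mask, 24)
        assert len(pairs) == 15
        np.testing.assert_array_equal(pairs[0][0].pixels, img.pixels)

    def test_full_turn_is_single_identity(self, rng):
        img = _image(rng.normal(size=(64, 64)))
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        pairs = preprocess.augment_rotations(img, mask, 360)
        assert len(pairs) == 1
        np.testing.assert_array_equal(pairs[0][0].pixels, img.pixels)

    def test_halfturn_of_point_symmetric_image_is_identity(self):
        n = 65
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        pix = np.exp(-(((yy - c) ** 2 + (xx - c) ** 2)) / 200.0)  # symmetric
        img = _image(pix)
        pairs = preprocess.augment_rotations(
            img, phantom.LesionMask(np.zeros((n, n), dtype=bool)), 180)
        np.testing.assert_allclose(pairs[1][0].pixels, pix, atol=1e-7)

    def test_nondivisor_step_rejected(self, rng):
        img = _image(rng.normal(size=(64, 64)))
        mask = phantom.LesionMask(np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError):
            preprocess.augment_rotations(img, mask, 25)


class TestBuildDataset:
    def test_class_ratio_near_unity(self, block_dataset):
        counts = block_dataset.counts
        assert 0.9 <= counts[1] / counts[0] <= 1.1

    def test_positive_only_filter_excludes_negative_images(self, cohort):
        ds = preprocess.build_dataset(cohort[:20], "positive_only",
                                      rotation_step=120,
                                      max_pos_per_rotation=5, seed=0)
        neg_ids = {i.image_id for i, _ in cohort if i.contrast_class == "negative"}
        assert not {b.source_image_id for b in ds.blocks} & neg_ids

    def test_rerun_same_seed_identical_hash(self, cohort):
        kw = dict(rotation_step=120, max_pos_per_rotation=5, seed=3)
        a = preprocess.build_dataset(cohort[:3], "positive_only", **kw)
        b = preprocess.build_dataset(cohort[:3], "positive_only", **kw)
        assert a.content_hash() == b.content_hash()

    def test_no_center_within_13_pixels_of_border(self, block_dataset):
        for b in block_dataset.blocks:
            r, c = b.center
            assert HALF_LO <= r <= 255 - HALF_HI
            assert HALF_LO <= c <= 255 - HALF_HI

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            preprocess.build_dataset([], "all")

    def test_subset_by_patient(self, block_dataset):
        pids = sorted(block_dataset.per_patient)
        sub = block_dataset.subset(pids[:2])
        assert {b.patient_id for b in sub.blocks} == set(pids[:2])
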