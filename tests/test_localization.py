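"""Template response against a brute-force oracle, the 0.9·max
thresholding rule, ROC sweep monotonicity and overlays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amcl import phantom
from amcl.localization import (ResponseMap, make_overlay, template_response,
                               threshold_response, threshold_sweep)
from amcl.preprocess import HALF_HI, HALF_LO


def _oracle_response(img, t):
    """Naive double-loop window sum-of-products."""
    h, w = img.shape
    out = np.zeros_like(img)
    for i in range(HALF_LO, h - HALF_HI):
        for j in range(HALF_LO, w - HALF_HI):
            win = img[i - HALF_LO:i + HALF_HI + 1, j - HALF_LO:j + HALF_HI + 1]
            out[i, j] = (win * t).sum()
    return out


class TestTemplateResponse:
    def test_constant_image_times_template_sum(self, rng):
        t = rng.normal(size=(28, 28))
        resp = template_response(np.full((40, 40), 2.5), t)
        np.testing.assert_allclose(resp.iconv[resp.valid_region],
                                   2.5 * t.sum(), atol=1e-9)
        assert not resp.iconv[~resp.valid_region].any()

    def test_impulse_template_sifts_image(self, rng):
        img = rng.normal(size=(40, 40))
        t = np.zeros((28, 28))
        t[HALF_LO, HALF_LO] = 1.0  # impulse at the window-center pixel
        resp = template_response(img, t)
        np.testing.assert_allclose(resp.iconv[resp.valid_region],
                                   img[resp.valid_region], atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            img = rng.normal(size=(rng.integers(30, 64), rng.integers(30, 64)))
            t = rng.normal(size=(28, 28))
            resp = template_response(img, t)
            np.testing.assert_allclose(resp.iconv, _oracle_response(img, t),
                                       atol=1e-9)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            template_response(rng.normal(size=(20, 40)),
                              rng.normal(size=(28, 28)))

    def test_flipped_variant_equals_correlation_with_rotated_kernel(self, rng):
        img = rng.normal(size=(40, 40))
        t = rng.normal(size=(28, 28))
        flipped = template_response(img, t, flip=True)
        rotated = template_response(img, t[::-1, ::-1])
        np.testing.assert_allclose(flipped.iconv, rotated.iconv, atol=1e-12)


class TestThreshold:
    def _resp(self, values):
        iconv = np.zeros((2, 2))
        iconv.flat[:len(values)] = values
        return ResponseMap(iconv=iconv, valid_region=np.ones((2, 2), bool))

    def test_keeps_values_at_or_above_ninety_percent_of_max(self):
        resp = self._resp([10.0, 9.5, 8.0, 1.0])
        res = threshold_response(resp, 0.9)
        kept = sorted(resp.iconv[res.predicted_mask])
        assert kept == [9.5, 10.0]

    def test_all_equal_positive_map_fully_kept(self):
        resp = self._resp([3.0, 3.0, 3.0, 3.0])
        assert threshold_response(resp, 0.9).predicted_mask.all()

    def test_thresholding_is_idempotent(self, rng):
        iconv = np.abs(rng.normal(size=(40, 40)))
        valid = np.zeros((40, 40), bool)
        valid[HALF_LO:40 - HALF_HI, HALF_LO:40 - HALF_HI] = True
        resp = ResponseMap(iconv * valid, valid)
        first = threshold_response(resp, 0.9)
        masked = ResponseMap(resp.iconv * first.predicted_mask,
                             resp.valid_region)
        second = threshold_response(masked, 0.9)
        np.testing.assert_array_equal(first.predicted_mask,
                                      second.predicted_mask)

    def test_nonpositive_maximum_gives_empty_mask(self):
        resp = self._resp([-1.0, -2.0, -3.0, -0.5])
        res = threshold_response(resp, 0.9)
        assert res.empty

    @pytest.mark.parametrize("frac", [0.0, -0.5, 1.5])
    def test_fraction_domain(self, frac):
        with pytest.raises(ValueError):
            threshold_response(self._resp([1.0]), frac)

    def test_brain_mask_gating_removes_outside_detections(self):
        resp = self._resp([10.0, 9.5, 9.5, 1.0])
        gate = np.array([[True, False], [True, True]])
        res = threshold_response(resp, 0.9, brain_mask=gate)
        assert res.predicted_mask.sum() == 2
        assert not res.predicted_mask[0, 1]


class TestSweep:
    @pytest.fixture()
    def resp_truth(self, rng):
        iconv = np.abs(rng.normal(size=(50, 50))) + 0.1
        valid = np.zeros((50, 50), bool)
        valid[HALF_LO:50 - HALF_HI, HALF_LO:50 - HALF_HI] = True
        truth = np.zeros((50, 50), bool)
        truth[20:28, 20:28] = True
        return ResponseMap(iconv * valid, valid), truth

    def test_tiny_fraction_keeps_everything(self, resp_truth):
        resp, truth = resp_truth
        row = threshold_sweep(resp, truth, [1e-9])[0]
        assert row["tpr"] == pytest.approx(1.0)
        assert row["fpr"] == pytest.approx(1.0)

    def test_fraction_one_keeps_only_argmax(self, resp_truth):
        resp, truth = resp_truth
        pred = threshold_response(resp, 1.0).predicted_mask
        assert pred.sum() == 1
        assert resp.iconv[pred][0] == resp.max_response()

    def test_tpr_nonincreasing_in_fraction(self, resp_truth):
        resp, truth = resp_truth
        fracs = np.linspace(0.05, 1.0, 12)
        tprs = [r["tpr"] for r in threshold_sweep(resp, truth, fracs)]
        assert all(a >= b - 1e-12 for a, b in zip(tprs, tprs[1:]))


class TestOverlay:
    def test_perfect_prediction_has_no_green_or_blue(self, rng):
        img = rng.normal(size=(30, 30))
        truth = np.zeros((30, 30), bool)
        truth[5:10, 5:10] = True
        rgb = make_overlay(img, truth, truth)
        green = (rgb[..., 1] == 1) & (rgb[..., 0] == 0)
        blue = (rgb[..., 2] == 1) & (rgb[..., 0] == 0)
        assert not green.any() and not blue.any()

    def test_missed_lesion_is_blue_only(self, rng):
        img = rng.normal(size=(30, 30))
        truth = np.zeros((30, 30), bool)
        truth[5:10, 5:10] = True
        rgb = make_overlay(img, truth, np.zeros_like(truth))
        blue = np.all(rgb == (0, 0, 1), axis=-1)
        assert blue.sum() == truth.sum()

    def test_color_counts_equal_confusion_counts(self, rng):
        from amcl.evaluation import confusion
        truth = rng.random((30, 30)) > 0.7
        pred = rng.random((30, 30)) > 0.7
        rgb = make_overlay(rng.normal(size=(30, 30)), truth, pred)
        c = confusion(pred, truth)
        assert np.all(rgb == (1, 0, 0), axis=-1).sum() == c.tp
        assert np.all(rgb == (0, 1, 0), axis=-1).sum() == c.fp
        assert np.all(rgb == (0, 0, 1), axis=-1).sum() == c.fn

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            make_overlay(rng.normal(size=(30, 30)),
                         np.zeros((30, 30), bool), np.zeros((20, 20), bool))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_threshold_superlevel_property(seed):
    """For any response map, the kept set is exactly the valid-region
    super-level set at 0.9 of the valid maximum."""
    rng = np.random.default_rng(seed)
    iconv = rng.normal(size=(34, 34))
    valid = np.zeros((34, 34), bool)
    valid[HALF_LO:34 - HALF_HI, HALF_LO:34 - HALF_HI] = True
    resp = ResponseMap(iconv * valid, valid)
    res = threshold_response(resp, 0.9)
    m = resp.max_response()
    if m <= 0:
        assert res.empty
    else:
        np.testing.assert_array_equal(res.predicted_mask,
                                      valid & (resp.iconv >= 0.9 * m))
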