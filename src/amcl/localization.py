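"""Template-convolution localization and segmentation.

The mean PIB is slid over the normalized image with stride one; at each
center (i, j) the response is the sum of the element-wise product of
the 28×28 window rows i−13…i+14 / columns j−13…j+14 with the template
(cross-correlation — no kernel flip).  Centers whose window does not
fit inside the frame are excluded from both the response and its
maximum.  The predicted lesion is the super-level set at 0.9 of the
maximum response (values below the threshold are zeroed; equality is
kept), a fraction originally chosen from the ROC curve and re-derivable
on phantoms via :func:`threshold_sweep`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .phantom import BrainImage, LesionMask
from .preprocess import BLOCK, HALF_LO, HALF_HI
from .activation_max import PatternImageBlock

__all__ = [
    "ResponseMap",
    "LocalizationResult",
    "template_response",
    "threshold_response",
    "threshold_sweep",
    "make_overlay",
]


@dataclass
class ResponseMap:
    """Stride-1 template response; entries outside ``valid_region``
    (centers without a full 28×28 window) are zero and excluded from
    any maximum."""

    iconv: np.ndarray
    valid_region: np.ndarray

    def max_response(self) -> float:
        if not self.valid_region.any():
            return float("-inf")
        return float(self.iconv[self.valid_region].max())


@dataclass
class LocalizationResult:
    predicted_mask: np.ndarray
    threshold_used: float
    max_response: float
    overlay: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.predicted_mask.any()


def _as_array(obj) -> np.ndarray:
    if isinstance(obj, BrainImage):
        return obj.pixels
    if isinstance(obj, PatternImageBlock):
        return obj.pixels
    if isinstance(obj, LesionMask):
        return obj.mask
    return np.asarray(obj)


def template_response(image, pib, *, flip: bool = False) -> ResponseMap:
    """Cross-correlate the normalized image with the 28×28 template at
    stride one (FFT-based; identical to the naive window sum).

    ``flip=True`` selects true convolution (kernel rotated 180°)
    instead of the default no-flip window product."""
    img = np.asarray(_as_array(image), dtype=float)
    t = np.asarray(_as_array(pib), dtype=float)
    if flip:
        t = t[::-1, ::-1]
    if t.shape != (BLOCK, BLOCK):
        raise ValueError("template must be 28×28")
    h, w = img.shape
    if h < BLOCK or w < BLOCK:
        raise ValueError("image smaller than the 28×28 template")
    resp_valid = correlate(img, t, mode="valid", method="auto")
    iconv = np.zeros_like(img)
    iconv[HALF_LO:h - HALF_HI, HALF_LO:w - HALF_HI] = resp_valid
    valid = np.zeros(img.shape, dtype=bool)
    valid[HALF_LO:h - HALF_HI, HALF_LO:w - HALF_HI] = True
    return ResponseMap(iconv=iconv, valid_region=valid)


def threshold_response(resp: ResponseMap, frac: float = 0.9,
                       brain_mask: np.ndarray | None = None
                       ) -> LocalizationResult:
    """Keep response values ≥ ``frac``·max (max over the valid region).

    A nonpositive maximum yields an empty prediction: the template
    matched nothing brighter than its own baseline.  ``brain_mask``
    optionally gates detections to the brain (off by default, mirroring
    skull-stripped inputs where the frame is already brain-only).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    m = resp.max_response()
    thr = frac * m
    if not np.isfinite(m) or m <= 0:
        mask = np.zeros_like(resp.valid_region)
    else:
        mask = resp.valid_region & (resp.iconv >= thr)
    if brain_mask is not None:
        mask = mask & np.asarray(brain_mask).astype(bool)
    return LocalizationResult(predicted_mask=mask, threshold_used=float(thr),
                              max_response=float(m))


def threshold_sweep(resp: ResponseMap, truth: LesionMask | np.ndarray,
                    fracs) -> list[dict]:
    """Pixel TPR/FPR over the valid region for each threshold fraction
    (the ROC table from which the 0.9 default can be re-derived)."""
    truth_arr = _as_array(truth).astype(bool)
    rows = []
    valid = resp.valid_region
    pos = truth_arr & valid
    neg = ~truth_arr & valid
    for frac in fracs:
        if not 0 < frac <= 1:
            raise ValueError("fracs must be in (0, 1]")
        pred = threshold_response(resp, frac).predicted_mask
        tpr = float((pred & pos).sum() / pos.sum()) if pos.any() else float("nan")
        fpr = float((pred & neg).sum() / neg.sum()) if neg.any() else float("nan")
        rows.append({"frac": float(frac), "tpr": tpr, "fpr": fpr})
    return rows


def make_overlay(image, truth, pred) -> np.ndarray:
    """RGB overlay on the grayscale image: red = true positive
    (truth∩pred), green = false positive (pred∖truth), blue = false
    negative (truth∖pred)."""
    img = np.asarray(_as_array(image), dtype=float)
    t = _as_array(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    if img.shape != t.shape or img.shape != p.shape:
        raise ValueError("overlay inputs must share one shape")
    lo, hi = img.min(), img.max()
    base = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[t & p] = (1.0, 0.0, 0.0)
    rgb[p & ~t] = (0.0, 1.0, 0.0)
    rgb[t & ~p] = (0.0, 0.0, 1.0)
    return rgb
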