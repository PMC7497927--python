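"""Grad-CAM comparator: class-activation maps from the last conv layer.

For a 28×28 block that the classifier calls lesion (probability > 0.5),
the channel weights are the spatially averaged gradients of the
pre-sigmoid class score with respect to the last convolutional feature
maps A^k (16 channels of 10×10 here, so the averaging pool Z = 100):

    α_k = (1/Z) Σ_ij ∂y/∂A^k_ij ,    L = ReLU(Σ_k α_k A^k) .

The per-block 10×10 maps are assembled into an image-level localization
by scanning blocks at quarter-window stride (4 px), bilinearly upsampling
each firing block's map to 28×28, accumulating into a canvas normalized
by per-pixel coverage, and binarizing with the same 0.9·max rule as the
template-convolution method so the two localizers are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .netpos import NetPosModel
from .preprocess import BLOCK
from .localization import LocalizationResult, _as_array

__all__ = ["GradCamBlockMap", "gradcam_block", "gradcam_localize"]


@dataclass
class GradCamBlockMap:
    """Per-block Grad-CAM quantities: channel weights α, feature maps
    A, the class probability, and the nonnegative map L."""

    weights: np.ndarray     # (K,)
    fm: np.ndarray          # (K, H, W)
    probability: float
    map: np.ndarray         # (H, W), >= 0 after ReLU

    def __post_init__(self):
        assert np.all(self.map >= 0)


def gradcam_block(model: NetPosModel, block: np.ndarray
                  ) -> GradCamBlockMap | None:
    """Grad-CAM map of one block, or None when the classifier does not
    call the block lesion (probability ≤ 0.5)."""
    block = np.asarray(block, dtype=float)
    if block.shape != (BLOCK, BLOCK):
        raise ValueError("block must be 28×28")
    fm, dfm, prob = model.feature_maps_and_grads(block)
    if prob <= 0.5:
        return None
    alpha = dfm.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(alpha, fm, axes=1), 0.0)
    return GradCamBlockMap(weights=alpha, fm=fm, probability=prob, map=cam)


def _batched_cams(model: NetPosModel, blocks: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, maps) for a batch of blocks in one fwd/bwd pass.

    Batch elements are independent, so backpropagating a vector of ones
    from the logits yields each block's own ∂logit/∂A."""
    from . import nn

    x = blocks[:, None]
    logits = model.net.forward(x)[:, 0]
    model.net.zero_grads()
    model.net.backward(np.ones((x.shape[0], 1)))
    fm = model.net.last_activations[model.GRADCAM_NODE]
    dfm = model.net.last_grads[model.GRADCAM_NODE]
    model.net.zero_grads()
    alpha = dfm.mean(axis=(2, 3))
    cams = np.maximum(np.einsum("nk,nkhw->nhw", alpha, fm), 0.0)
    return nn.sigmoid(logits), cams


def gradcam_localize(model: NetPosModel, image, frac: float = 0.9,
                     stride: int = 4) -> LocalizationResult:
    """Image-level Grad-CAM localization.

    Scans 28×28 blocks at ``stride`` plus the flush-right/bottom
    positions.  The default stride of 4 keeps every image point within
    ~3 px of some block center, inside the patch classifier's firing
    radius for a centered lesion; coarser grids can step entirely over
    a small lesion.  Blocks with probability > 0.5 fire;
    upsamples their maps to 28×28 and accumulates them into a
    coverage-normalized heatmap, binarized at ``frac``·max.  The
    heatmap is returned in ``extras['heatmap']``.
    """
    img = np.asarray(_as_array(image), dtype=float)
    h, w = img.shape
    if h < BLOCK or w < BLOCK:
        raise ValueError("image smaller than one block")

    def starts(dim):
        s = list(range(0, dim - BLOCK + 1, stride))
        if s[-1] != dim - BLOCK:
            s.append(dim - BLOCK)
        return s

    rows, cols = starts(h), starts(w)
    positions = [(r, c) for r in rows for c in cols]
    blocks = np.stack([img[r:r + BLOCK, c:c + BLOCK] for r, c in positions])
    canvas = np.zeros_like(img)
    coverage = np.zeros_like(img)
    n_fired = 0
    for lo in range(0, len(positions), 512):
        probs, cams = _batched_cams(model, blocks[lo:lo + 512])
        for (r, c), p, cam in zip(positions[lo:lo + 512], probs, cams):
            if p <= 0.5:
                continue
            n_fired += 1
            up = _sk_resize(cam, (BLOCK, BLOCK), order=1, preserve_range=True,
                            anti_aliasing=False)
            canvas[r:r + BLOCK, c:c + BLOCK] += up
            coverage[r:r + BLOCK, c:c + BLOCK] += 1.0
    heat = np.zeros_like(img)
    covered = coverage > 0
    heat[covered] = canvas[covered] / coverage[covered]
    m = float(heat.max()) if covered.any() else 0.0
    if m <= 0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        mask = heat >= frac * m
    return LocalizationResult(predicted_mask=mask, threshold_used=frac * m,
                              max_response=m,
                              extras={"heatmap": heat, "n_fired": n_fired})
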