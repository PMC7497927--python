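"""Image normalization and 28×28 block-dataset construction.

The training data for the patch classifier are 28×28 blocks cut from
normalized brain images:

* images are resampled to a uniform 256×256 grid (bilinear; masks
  nearest-neighbor) and z-scored to zero mean / unit variance over the
  brain mask,
* a *positive* (lesion) block is any 28×28 window, centered on a lesion
  pixel, that contains more than 4/5 of the window's pixels as lesion
  OR at least 4/5 of the lesion's total pixels (the "4/5 rules"),
* *negative* (normal) blocks are sampled in equal thirds from three
  lesion-free regions N1–N3 placed symmetrically with respect to the
  image center (N1 is the point reflection of the lesion's bounding
  box, dilated by 14 px; N2/N3 mirror N1 across the vertical and
  horizontal midlines); a candidate is excluded if its window or the
  point reflection of its window touches the lesion,
* each source image is additionally rotated in 24° steps and block
  extraction repeated per rotation, balancing positives and negatives.

Window convention: the block centered at (r, c) spans rows r−13…r+14
and columns c−13…c+14 (0-based, inclusive) — the same indexing used by
the template-convolution stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

from .phantom import BrainImage, LesionMask

__all__ = [
    "HALF_LO",
    "HALF_HI",
    "BLOCK",
    "ImageBlock",
    "BlockDataset",
    "resize_to_grid",
    "zscore_normalize",
    "is_lesion_block",
    "extract_positive_blocks",
    "extract_negative_blocks",
    "augment_rotations",
    "build_dataset",
]

BLOCK = 28
HALF_LO, HALF_HI = 13, 14  # window = [center−13, center+14] inclusive


@dataclass
class ImageBlock:
    """One 28×28 training block with label and provenance."""

    pixels: np.ndarray
    label: int
    center: tuple[int, int]
    angle: float
    source_image_id: str
    patient_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (BLOCK, BLOCK):
            raise ValueError("block pixels must be 28×28")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class BlockDataset:
    """A labelled block collection with per-patient provenance."""

    blocks: list[ImageBlock] = field(default_factory=list)

    @property
    def counts(self) -> dict[int, int]:
        c = {0: 0, 1: 0}
        for b in self.blocks:
            c[b.label] += 1
        return c

    @property
    def per_patient(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for i, b in enumerate(self.blocks):
            idx.setdefault(b.patient_id, []).append(i)
        return idx

    def subset(self, patient_ids) -> "BlockDataset":
        keep = set(patient_ids)
        return BlockDataset([b for b in self.blocks if b.patient_id in keep])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for b in self.blocks:
            h.update(np.ascontiguousarray(b.pixels).tobytes())
            h.update(f"{b.label}|{b.center}|{b.angle}|{b.source_image_id}".encode())
        return h.hexdigest()

    def __len__(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def resize_to_grid(image: BrainImage, target: int = 256,
                   lesion: LesionMask | None = None):
    """Bilinearly resample an image to ``target``×``target``; masks are
    resampled nearest-neighbor and re-binarized.  Returns the image, or
    ``(image, lesion)`` when a lesion mask is supplied."""
    if target < BLOCK:
        raise ValueError(f"target grid must be at least {BLOCK}")
    if image.pixels.shape == (target, target):
        out = BrainImage(image.pixels.copy(), image.brain_mask.copy(),
                         image.patient_id, image.image_id,
                         image.contrast_class, dict(image.meta))
        les = LesionMask(lesion.mask.copy()) if lesion is not None else None
    else:
        pix = _sk_resize(image.pixels, (target, target), order=1,
                         preserve_range=True, anti_aliasing=False)
        bm = _sk_resize(image.brain_mask.astype(float), (target, target),
                        order=0, preserve_range=True) > 0.5
        out = BrainImage(pix, bm, image.patient_id, image.image_id,
                         image.contrast_class, dict(image.meta))
        les = None
        if lesion is not None:
            lm = _sk_resize(lesion.mask.astype(float), (target, target),
                            order=0, preserve_range=True) > 0.5
            les = LesionMask(lm)
    return out if lesion is None else (out, les)


def zscore_normalize(image: BrainImage) -> BrainImage:
    """Zero-mean / unit-variance normalization over the brain mask
    (population variance); pixels outside the mask are set to 0."""
    vals = image.pixels[image.brain_mask]
    mean = float(vals.mean())
    sd = float(vals.std())  # population (n) SD
    if sd < 1e-12:
        raise ValueError("constant image inside brain mask: z-score undefined")
    pix = np.zeros_like(image.pixels)
    pix[image.brain_mask] = (vals - mean) / sd
    meta = dict(image.meta, zscore=(mean, sd))
    return BrainImage(pix, image.brain_mask.copy(), image.patient_id,
                      image.image_id, image.contrast_class, meta)


# ---------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------

def _sat(mask: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border row/column."""
    s = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    return s


def _rect_sum(s: np.ndarray, r0, r1, c0, c1):
    """Inclusive-rectangle sums [r0..r1]×[c0..c1] from a SAT (vectorized)."""
    return s[r1 + 1, c1 + 1] - s[r0, c1 + 1] - s[r1 + 1, c0] + s[r0, c0]


def _window_counts(mask: np.ndarray) -> np.ndarray:
    """(H−27)×(W−27) array of 28×28-window sums; entry (i, j) is the
    window centered at (i+13, j+13)."""
    s = _sat(mask)
    return (s[BLOCK:, BLOCK:] - s[:-BLOCK, BLOCK:]
            - s[BLOCK:, :-BLOCK] + s[:-BLOCK, :-BLOCK])


def _valid_center(center, shape) -> bool:
    r, c = center
    return (HALF_LO <= r <= shape[0] - HALF_HI - 1
            and HALF_LO <= c <= shape[1] - HALF_HI - 1)


def is_lesion_block(center: tuple[int, int], mask: LesionMask) -> bool:
    """The 4/5 coverage rules: the window centered at ``center`` is a
    lesion block iff its lesion-pixel count exceeds 4/5 of the window
    area, or contains at least 4/5 of all lesion pixels."""
    m = mask.mask
    r, c = center
    if not _valid_center(center, m.shape):
        raise ValueError(f"window at {center} does not fit inside {m.shape}")
    n_in = int(m[r - HALF_LO:r + HALF_HI + 1, c - HALF_LO:c + HALF_HI + 1].sum())
    total = int(m.sum())
    return n_in > 0.8 * BLOCK * BLOCK or (total > 0 and n_in >= 0.8 * total)


def _extract(image: BrainImage, centers, label, angle) -> list[ImageBlock]:
    out = []
    for r, c in centers:
        pix = image.pixels[r - HALF_LO:r + HALF_HI + 1,
                           c - HALF_LO:c + HALF_HI + 1]
        out.append(ImageBlock(pix.copy(), label, (int(r), int(c)), angle,
                              image.image_id, image.patient_id))
    return out


def extract_positive_blocks(image: BrainImage, mask: LesionMask,
                            *, angle: float = 0.0,
                            max_blocks: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> list[ImageBlock]:
    """All lesion blocks: every lesion pixel (whose window fits) is
    tried as a center and kept iff it passes the 4/5 rules.

    ``max_blocks`` optionally subsamples the qualifying centers without
    replacement (seeded via ``rng``) to bound dataset size.
    """
    m = mask.mask
    total = int(m.sum())
    if total == 0:
        return []
    h, w = m.shape
    counts = _window_counts(m)
    rr, cc = np.nonzero(m)
    ok = ((rr >= HALF_LO) & (rr <= h - HALF_HI - 1)
          & (cc >= HALF_LO) & (cc <= w - HALF_HI - 1))
    rr, cc = rr[ok], cc[ok]
    n_in = counts[rr - HALF_LO, cc - HALF_LO]
    keep = (n_in > 0.8 * BLOCK * BLOCK) | (n_in >= 0.8 * total)
    centers = list(zip(rr[keep], cc[keep]))
    if max_blocks is not None and len(centers) > max_blocks:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(centers), size=max_blocks, replace=False)
        centers = [centers[i] for i in sorted(idx)]
    return _extract(image, centers, 1, angle)


def _region_centers(rect, shape):
    """Valid window centers inside an (r0, r1, c0, c1) inclusive rect."""
    h, w = shape
    r0 = max(rect[0], HALF_LO)
    r1 = min(rect[1], h - HALF_HI - 1)
    c0 = max(rect[2], HALF_LO)
    c1 = min(rect[3], w - HALF_HI - 1)
    if r0 > r1 or c0 > c1:
        return np.empty((0, 2), dtype=int)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    return np.column_stack([rr.ravel(), cc.ravel()])


def negative_regions(mask: LesionMask, shape) -> list[tuple[int, int, int, int]]:
    """The three center-symmetric normal-sampling regions N1–N3.

    N1 = point reflection of the lesion bounding box through the image
    center, dilated by 14 px; N2 and N3 mirror N1 across the vertical
    and horizontal midlines.  For a lesion-free image the whole frame is
    a single region.
    """
    h, w = shape
    m = mask.mask
    if not m.any():
        return [(0, h - 1, 0, w - 1)]
    rr, cc = np.nonzero(m)
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    # point reflection through the image center (r -> H−1−r)
    n1 = (h - 1 - r1 - 14, h - 1 - r0 + 14, w - 1 - c1 - 14, w - 1 - c0 + 14)
    # mirror across vertical midline (columns flip), rows as N1
    n2 = (n1[0], n1[1], w - 1 - n1[3], w - 1 - n1[2])
    # mirror across horizontal midline (rows flip), columns as N1
    n3 = (h - 1 - n1[1], h - 1 - n1[0], n1[2], n1[3])
    return [n1, n2, n3]


def extract_negative_blocks(image: BrainImage, mask: LesionMask,
                            n_required: int, *, angle: float = 0.0,
                            rng: np.random.Generator | None = None
                            ) -> tuple[list[ImageBlock], bool]:
    """Sample ``n_required`` normal blocks, one third from each of the
    regions N1–N3.

    A candidate center must lie inside the brain, its window must
    contain zero lesion pixels, and the point reflection of its window
    through the image center must also be lesion-free.  Returns
    ``(blocks, shortfall)`` where ``shortfall`` flags that fewer than
    ``n_required`` candidates existed.
    """
    if n_required < 0:
        raise ValueError("n_required must be >= 0")
    rng = rng or np.random.default_rng(0)
    m = mask.mask
    h, w = m.shape
    s = _sat(m)

    def admissible(centers):
        if centers.shape[0] == 0:
            return centers
        r, c = centers[:, 0], centers[:, 1]
        inside = image.brain_mask[r, c]
        r, c = r[inside], c[inside]
        if r.size == 0:
            return np.empty((0, 2), dtype=int)
        win = _rect_sum(s, r - HALF_LO, r + HALF_HI, c - HALF_LO, c + HALF_HI)
        # reflected window of [r−13, r+14] is [H−1−r−14, H−1−r+13]
        rr, cc = (h - 1) - r, (w - 1) - c
        ok_ref = (rr - HALF_HI >= 0) & (rr + HALF_LO <= h - 1) \
            & (cc - HALF_HI >= 0) & (cc + HALF_LO <= w - 1)
        ref = np.zeros_like(win)
        ref[ok_ref] = _rect_sum(s, rr[ok_ref] - HALF_HI, rr[ok_ref] + HALF_LO,
                                cc[ok_ref] - HALF_HI, cc[ok_ref] + HALF_LO)
        keep = (win == 0) & ok_ref & (ref == 0)
        return np.column_stack([r[keep], c[keep]])

    regions = [admissible(_region_centers(rect, m.shape))
               for rect in negative_regions(mask, m.shape)]
    quota = [n_required // 3] * 3
    for i in range(n_required % 3):
        quota[i] += 1
    if len(regions) == 1:
        quota = [n_required]

    chosen: list[tuple[int, int]] = []
    leftovers: list[np.ndarray] = []
    for cand, q in zip(regions, quota):
        take = min(q, cand.shape[0])
        idx = rng.choice(cand.shape[0], size=take, replace=False) \
            if cand.shape[0] else np.empty(0, dtype=int)
        sel = np.zeros(cand.shape[0], dtype=bool)
        sel[idx] = True
        chosen.extend(map(tuple, cand[sel]))
        leftovers.append(cand[~sel])
    # top up from remaining candidates if some region ran short
    deficit = n_required - len(chosen)
    if deficit > 0:
        pool = np.concatenate(leftovers) if leftovers else np.empty((0, 2), int)
        take = min(deficit, pool.shape[0])
        if take:
            idx = rng.choice(pool.shape[0], size=take, replace=False)
            chosen.extend(map(tuple, pool[idx]))
    shortfall = len(chosen) < n_required
    return _extract(image, chosen, 0, angle), shortfall


# ---------------------------------------------------------------------
# rotation augmentation
# ---------------------------------------------------------------------

def augment_rotations(image: BrainImage, mask: LesionMask,
                      step_deg: float = 24.0
                      ) -> list[tuple[BrainImage, LesionMask]]:
    """Rotate the image/mask pair about the image center at every
    multiple of ``step_deg`` in [0°, 360°).  Intensities are bilinear,
    masks nearest-neighbor; out-of-frame pixels take the background
    level.  ``step_deg`` must divide 360."""
    if not (0 < step_deg <= 360) or 360 % step_deg != 0:
        raise ValueError("rotation step must divide 360")
    outside = ~image.brain_mask
    cval = float(np.median(image.pixels[outside])) if outside.any() else 0.0
    pairs = []
    for k in range(int(360 // step_deg)):
        angle = k * step_deg
        if angle == 0:
            img, les = image, mask
        else:
            pix = _sk_rotate(image.pixels, angle, order=1, preserve_range=True,
                             cval=cval)
            bm = _sk_rotate(image.brain_mask.astype(float), angle, order=0,
                            preserve_range=True, cval=0.0) > 0.5
            lm = _sk_rotate(mask.mask.astype(float), angle, order=0,
                            preserve_range=True, cval=0.0) > 0.5
            img = BrainImage(pix, bm, image.patient_id, image.image_id,
                             image.contrast_class,
                             dict(image.meta, angle=angle))
            les = LesionMask(lm)
        pairs.append((img, les))
    return pairs


# ---------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------

def build_dataset(cohort, contrast_filter: str = "positive_only", *,
                  target: int = 256, rotation_step: float = 24.0,
                  max_pos_per_rotation: int | None = None,
                  seed: int = 0) -> BlockDataset:
    """Build the balanced block dataset from a cohort.

    ``contrast_filter='positive_only'`` restricts sources to
    visible-lesion images (the configuration used to train the main
    classifier); ``'all'`` uses every image.  Per rotated image pair,
    positives are extracted exhaustively (optionally capped at
    ``max_pos_per_rotation``) and an equal number of negatives is drawn
    from the N1–N3 regions, so the class ratio stays ≈1:1.
    """
    if contrast_filter not in ("positive_only", "all"):
        raise ValueError("contrast_filter must be 'positive_only' or 'all'")
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    ds = BlockDataset()
    for image, lesion in cohort:
        if contrast_filter == "positive_only" and image.contrast_class != "positive":
            continue
        img_r, les_r = resize_to_grid(image, target, lesion)
        img_n = zscore_normalize(img_r)
        for img_rot, les_rot in augment_rotations(img_n, les_r, rotation_step):
            angle = float(img_rot.meta.get("angle", 0.0))
            pos = extract_positive_blocks(img_rot, les_rot, angle=angle,
                                          max_blocks=max_pos_per_rotation,
                                          rng=rng)
            if not pos:
                continue
            neg, _short = extract_negative_blocks(img_rot, les_rot, len(pos),
                                                  angle=angle, rng=rng)
            ds.blocks.extend(pos)
            ds.blocks.extend(neg)
    return ds
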