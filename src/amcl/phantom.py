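"""Synthetic 2D pseudo-FLAIR brain phantoms with ground-truth lesions.

Clinical FLAIR slices of focal cortical dysplasia are not publicly
deposited, so every downstream stage of the method is exercised on
phantoms that reproduce the statistical structure the method assumes:

* an elliptical "brain" on a dark background, with a brighter cortical
  band along its rim (the tissue where the lesions live),
* at most one roughly disc-shaped lesion embedded in the band, with a
  flat bright core and a smooth Gaussian-profile edge — the core exceeds
  its immediate surround by exactly ``lesion_contrast`` before noise,
* a lesion-free point reflection of the lesion region through the image
  center (subtle lesions break the brain's approximate central
  symmetry; the contralateral side is healthy),
* optional diffuse bright "distractor" blobs away from the lesion,
  mimicking normally-bright structures such as the temporal lobes,
* i.i.d. Gaussian noise inside the brain.

Two contrast presets define the study conditions: ``positive`` lesions
(8× the noise SD, clearly visible) and ``negative`` lesions (2× the
noise SD, subvisible — the regime the method targets).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomParams",
    "BrainImage",
    "LesionMask",
    "PlacementError",
    "make_phantom",
    "make_cohort",
    "make_reference_cohort",
    "write_cohort",
    "read_cohort",
    "POSITIVE_SNR",
    "NEGATIVE_SNR",
]

#: lesion-contrast-to-noise ratios of the two presets
POSITIVE_SNR = 8.0
NEGATIVE_SNR = 2.0

#: reference patient/image layout of the emulated cohort:
#: 7 lesion-visible patients carrying 16 images, 12 subvisible-lesion
#: patients carrying 18 images (34 images, 19 patients in total)
REFERENCE_POSITIVE_IMAGES = (3, 3, 2, 2, 2, 2, 2)
REFERENCE_NEGATIVE_IMAGES = (2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1)


class PlacementError(RuntimeError):
    """Raised when no lesion position satisfies the geometric
    constraints after bounded retries."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity settings of one phantom.

    Intensities are arbitrary units (the pipeline z-scores everything).
    ``brain_axes``, ``cortex_band_width`` and ``lesion_radius_range``
    default to fractions of ``image_size`` chosen so a 28×28 analysis
    window behaves on a 256×256 phantom the way it does on a resampled
    clinical slice.
    """

    image_size: int = 256
    brain_axes: tuple[float, float] | None = None   # (semi-x, semi-y) px
    cortex_band_width: float | None = None          # px, radial
    background_level: float = 0.0
    brain_level: float = 0.50
    cortex_level: float = 0.58
    sulcal_amp: float = 5.0      # px, undulation of the inner cortex edge
    sulcal_freq: int = 19        # undulation periods around the brain
    noise_sd: float = 0.03
    psf_sigma: float = 1.5
    lesion_radius_range: tuple[float, float] | None = None
    lesion_contrast: float = POSITIVE_SNR * 0.03
    contrast_class: str = "positive"
    distractor_count: int = 2
    distractor_amplitude: float = 0.02
    distractor_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be positive")
        if self.lesion_radius_range is not None and self.lesion_radius_range[0] < 5:
            raise ValueError("minimum lesion radius must be >= 5 px")
        if self.contrast_class not in ("positive", "negative"):
            raise ValueError("contrast_class must be 'positive' or 'negative'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    # resolved geometry -------------------------------------------------
    @property
    def axes(self) -> tuple[float, float]:
        if self.brain_axes is not None:
            return self.brain_axes
        s = self.image_size
        return (0.39 * s, 0.33 * s)

    @property
    def band_width(self) -> float:
        if self.cortex_band_width is not None:
            return self.cortex_band_width
        return 0.133 * self.image_size

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.lesion_radius_range is not None:
            return self.lesion_radius_range
        s = self.image_size
        return (max(5.0, 0.0215 * s), max(6.0, 0.0293 * s))

    # presets -----------------------------------------------------------
    def preset(self, contrast_class: str, **overrides) -> "PhantomParams":
        """Copy with the lesion contrast of the given class
        (positive: 8× noise SD; negative: 2× noise SD)."""
        snr = {"positive": POSITIVE_SNR, "negative": NEGATIVE_SNR}[contrast_class]
        return dataclasses.replace(
            self, lesion_contrast=snr * self.noise_sd,
            contrast_class=contrast_class, **overrides)


@dataclass
class BrainImage:
    """One 2D intensity slice plus brain mask and identity."""

    pixels: np.ndarray
    brain_mask: np.ndarray
    patient_id: str
    image_id: str
    contrast_class: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.pixels.shape != self.brain_mask.shape:
            raise ValueError("pixels and brain_mask shape mismatch")
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")


@dataclass
class LesionMask:
    """Binary ground-truth lesion map aligned to a BrainImage."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    def validate_against(self, image: BrainImage) -> None:
        if self.mask.shape != image.pixels.shape:
            raise ValueError("lesion mask shape mismatch")
        if np.any(self.mask & ~image.brain_mask):
            raise ValueError("lesion pixels outside brain mask")


# ---------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------

def _ellipse_rho(shape: tuple[int, int], axes: tuple[float, float]) -> np.ndarray:
    """Normalized elliptical radius (1 on the brain boundary)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return np.sqrt(((xx - cx) / axes[0]) ** 2 + ((yy - cy) / axes[1]) ** 2)


def _lesion_profile(shape, center, radius, contrast):
    """Flat-top disc with a Gaussian shoulder, truncated at ``radius``.

    The profile equals ``contrast`` on the flat core (r <= 0.7·radius,
    lesional hyperintensity is fairly homogeneous) and decays to
    ~0.02·contrast at the truncation edge, so the mean over the core
    minus the mean over any region outside the support disc is exactly
    ``contrast`` on a locally uniform background.

    Returns ``(profile, mask, support, core)``: the ground-truth
    ``mask`` is the half-maximum contour (profile >= contrast/2), the
    way a rater traces the visible extent of a blurred lesion;
    ``support`` is the full truncation disc outside which the profile
    is exactly zero.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - center[0], xx - center[1])
    core = 0.7 * radius
    sigma = (radius - core) / 2.0
    prof = np.where(r <= core, 1.0, np.exp(-((r - core) / sigma) ** 2))
    prof[r > radius] = 0.0
    prof = contrast * prof
    return prof, prof >= 0.5 * contrast, r <= radius, r <= core


def make_phantom(params: PhantomParams, lesion_present: bool = True
                 ) -> tuple[BrainImage, LesionMask]:
    """Generate one phantom and its ground-truth lesion mask.

    The lesion (if present) is placed so that a 4-px ring around it
    still lies in the uniform cortical band and so that its point
    reflection through the image center is lesion-free; placement is
    retried up to 200 times before :class:`PlacementError` is raised.
    Same params (including seed) → bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    shape = (n, n)
    axes = params.axes
    rho = _ellipse_rho(shape, axes)
    brain_mask = rho <= 1.0
    rho0 = 1.0 - params.band_width / min(axes)
    # the inner cortex boundary undulates (folded gyri): a straight
    # GM/WM interface at window scale would be anatomically wrong
    cy0, cx0 = (n - 1) / 2.0, (n - 1) / 2.0
    yy0, xx0 = np.mgrid[0:n, 0:n]
    phi = np.arctan2(yy0 - cy0, xx0 - cx0)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = (params.sulcal_amp / min(axes)) * np.sin(
        params.sulcal_freq * phi + phase)
    band = (rho >= rho0 + wobble) & brain_mask

    pixels = np.full(shape, params.background_level, dtype=float)
    pixels[brain_mask] = params.brain_level
    pixels[band] = params.cortex_level
    if params.psf_sigma > 0:
        # point-spread blur of the anatomy: tissue interfaces in MR are
        # partial-volume ramps, not step edges; the kernel is truncated
        # at 3σ so its reach is exactly the placement margin below
        from scipy.ndimage import gaussian_filter
        pixels = gaussian_filter(pixels, params.psf_sigma, mode="nearest",
                                 truncate=3.0)

    center_img = ((n - 1) / 2.0, (n - 1) / 2.0)
    mask = np.zeros(shape, dtype=bool)
    meta: dict = {"band_rho0": rho0}

    lesion_center = None
    lesion_radius = None
    if lesion_present:
        rho_mid = (rho0 + 1.0) / 2.0
        for _ in range(200):
            radius = rng.uniform(*params.radius_range)
            phi = rng.uniform(0, 2 * np.pi)
            cy = center_img[0] + rho_mid * axes[1] * np.sin(phi)
            cx = center_img[1] + rho_mid * axes[0] * np.cos(phi)
            cy, cx = round(cy), round(cx)
            # the 4-px ring around the lesion must sit on a uniform
            # background: inside the band, clear of the PSF kernel reach
            yy, xx = np.mgrid[0:n, 0:n]
            kernel_radius = int(3.0 * params.psf_sigma + 0.5)
            margin = radius + 4.0 + kernel_radius
            disc_ext = np.hypot(yy - cy, xx - cx) <= margin
            if not np.all(band[disc_ext]):
                continue
            # contralateral (point-reflected) region must be lesion-free:
            # with one lesion this means the reflection cannot overlap it
            ry, rx = (n - 1) - cy, (n - 1) - cx
            if np.hypot(ry - cy, rx - cx) <= 2 * radius + 4.0:
                continue
            lesion_center, lesion_radius = (cy, cx), radius
            break
        else:
            raise PlacementError("could not place lesion inside cortical band")
        prof, mask, support, core = _lesion_profile(
            shape, lesion_center, lesion_radius, params.lesion_contrast)
        pixels += prof
        meta.update(lesion_center=lesion_center, lesion_radius=lesion_radius,
                    core_mask_area=int(core.sum()),
                    support_radius=lesion_radius)

    # distractors: diffuse bright blobs in the band, away from the lesion
    placed = 0
    for _ in range(50 * max(1, params.distractor_count)):
        if placed >= params.distractor_count:
            break
        phi = rng.uniform(0, 2 * np.pi)
        rho_d = rng.uniform(rho0 + 0.05, 0.95)
        dy = center_img[0] + rho_d * axes[1] * np.sin(phi)
        dx = center_img[1] + rho_d * axes[0] * np.cos(phi)
        if lesion_center is not None:
            if np.hypot(dy - lesion_center[0], dx - lesion_center[1]) < \
                    lesion_radius + 28.0 + params.distractor_sigma:
                continue
        yy, xx = np.mgrid[0:n, 0:n]
        blob = np.exp(-((yy - dy) ** 2 + (xx - dx) ** 2)
                      / (2 * params.distractor_sigma ** 2))
        pixels += params.distractor_amplitude * blob * brain_mask
        placed += 1

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=shape)
        pixels[brain_mask] += noise[brain_mask]

    image = BrainImage(pixels=pixels, brain_mask=brain_mask,
                       patient_id="", image_id="",
                       contrast_class=params.contrast_class, meta=meta)
    lesion = LesionMask(mask=mask)
    lesion.validate_against(image)
    return image, lesion


def _jitter_params(params: PhantomParams, rng: np.random.Generator
                   ) -> PhantomParams:
    """Per-patient geometry perturbation: ±10% on the brain semi-axes."""
    ax = params.axes
    f = rng.uniform(0.9, 1.1, size=2)
    return dataclasses.replace(params, brain_axes=(ax[0] * f[0], ax[1] * f[1]))


def make_cohort(n_patients: int, images_per_patient, positive_fraction: float,
                params: PhantomParams | None = None, seed: int = 0
                ) -> list[tuple[BrainImage, LesionMask]]:
    """Generate a multi-patient cohort in deterministic order.

    Each patient gets a fixed geometry perturbation shared by all of
    their images, and a per-patient contrast class (the first
    ``round(positive_fraction·n_patients)`` patients are positive).
    ``images_per_patient`` is an int, a per-patient sequence, or None —
    None selects the reference 19-patient / 34-image layout (16
    positive-class and 18 negative-class images).
    """
    if n_patients < 2:
        raise ValueError("cohort needs at least 2 patients")
    params = params or PhantomParams()
    if images_per_patient is None:
        if n_patients != 19:
            raise ValueError("the reference image layout requires 19 patients")
        counts = list(REFERENCE_POSITIVE_IMAGES) + list(REFERENCE_NEGATIVE_IMAGES)
        n_positive = len(REFERENCE_POSITIVE_IMAGES)
    else:
        if np.isscalar(images_per_patient):
            counts = [int(images_per_patient)] * n_patients
        else:
            counts = [int(c) for c in images_per_patient]
            if len(counts) != n_patients:
                raise ValueError("images_per_patient length != n_patients")
        n_positive = int(round(positive_fraction * n_patients))

    cohort: list[tuple[BrainImage, LesionMask]] = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        cls = "positive" if p < n_positive else "negative"
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(p,)))
        pparams = _jitter_params(params.preset(cls), prng)
        for j in range(counts[p]):
            img_seed = int(prng.integers(2 ** 31))
            iparams = dataclasses.replace(pparams, seed=img_seed)
            image, lesion = make_phantom(iparams, lesion_present=True)
            image.patient_id = pid
            image.image_id = f"{pid}_{j + 1}"
            cohort.append((image, lesion))
    return cohort


def make_reference_cohort(params: PhantomParams | None = None, seed: int = 0
                          ) -> list[tuple[BrainImage, LesionMask]]:
    """The emulated study cohort: 19 patients, 16 visible-lesion images
    (7 patients) and 18 subvisible-lesion images (12 patients)."""
    return make_cohort(19, None, 7 / 19, params, seed)


# ---------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------

def write_cohort(cohort, outdir, fmt: str = "nii") -> Path:
    """Write image/mask pairs plus a CSV manifest; returns manifest path.

    ``fmt='nii'`` stores float32 single-slice NIfTI (.nii.gz); ``'png'``
    stores 8-bit PNGs with the intensity window recorded in the manifest
    so images can be mapped back to intensity units on load.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image, lesion in cohort:
        stem = image.image_id or "image"
        if fmt == "nii":
            import nibabel as nib
            ipath = outdir / f"{stem}.nii.gz"
            mpath = outdir / f"{stem}_mask.nii.gz"
            nib.save(nib.Nifti1Image(
                image.pixels.astype(np.float32)[..., None], np.eye(4)), ipath)
            nib.save(nib.Nifti1Image(
                lesion.mask.astype(np.uint8)[..., None], np.eye(4)), mpath)
            vmin = vmax = np.nan
        elif fmt == "png":
            import imageio.v3 as iio
            ipath = outdir / f"{stem}.png"
            mpath = outdir / f"{stem}_mask.png"
            vmin, vmax = float(image.pixels.min()), float(image.pixels.max())
            scale = 255.0 / (vmax - vmin) if vmax > vmin else 1.0
            iio.imwrite(ipath, ((image.pixels - vmin) * scale).astype(np.uint8))
            iio.imwrite(mpath, (lesion.mask * 255).astype(np.uint8))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        rows.append(dict(patient_id=image.patient_id, image_id=image.image_id,
                         contrast_class=image.contrast_class,
                         image_path=ipath.name, mask_path=mpath.name,
                         vmin=vmin, vmax=vmax))
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[tuple[BrainImage, LesionMask]]:
    """Load a cohort written by :func:`write_cohort`.

    The brain mask is reconstructed as the set of pixels above the
    background level (phantom backgrounds are flat)."""
    import pandas as pd

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cohort = []
    for row in df.itertuples(index=False):
        ipath, mpath = root / row.image_path, root / row.mask_path
        if ipath.suffix == ".gz" or ipath.suffix == ".nii":
            import nibabel as nib
            pixels = np.asarray(nib.load(str(ipath)).dataobj, dtype=float)[..., 0]
            mask = np.asarray(nib.load(str(mpath)).dataobj)[..., 0] > 0
        else:
            import imageio.v3 as iio
            raw = iio.imread(ipath).astype(float)
            if np.isfinite(row.vmax) and row.vmax > row.vmin:
                pixels = raw / 255.0 * (row.vmax - row.vmin) + row.vmin
            else:
                pixels = raw
            mask = iio.imread(mpath) > 0
        bg = float(np.median(pixels[[0, -1], :]))
        brain = pixels > bg + 0.2 * (float(pixels.max()) - bg)
        image = BrainImage(pixels=pixels, brain_mask=brain,
                           patient_id=str(row.patient_id),
                           image_id=str(row.image_id),
                           contrast_class=str(row.contrast_class))
        cohort.append((image, LesionMask(mask=mask)))
    return cohort
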