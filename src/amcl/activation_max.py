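"""Pattern-image-block (PIB) synthesis by activation maximization.

A PIB is a synthetic 28×28 template distilled from the trained patch
classifier: starting from seeded uniform noise, the input pixels are
optimized by gradient ascent on the output neuron (ascent for the
lesion target, descent for the normal target).  Optimizing a full-size
28×28 image directly yields high-frequency speckle, so the pixels are
optimized multi-scale: the working image starts at 7×7 and is
alternately (a) resized to 28×28, z-scored and updated for 20 gradient
steps, then mapped back to its working scale, and (b) upscaled by ×1.2
and smoothed with a 2×2 box blur, for 8 rounds.  The result is a
low-frequency template that drives the classifier to a probability of
~1 (lesion) or ~0 (normal).

Gradient steps use the pre-sigmoid logit as the objective (the sigmoid
is monotone, so the argmax is unchanged while the gradient never
saturates) and are normalized by the max-abs gradient, making the step
size scale-free.  The probability is what is reported.

The mean of four independently seeded runs is the template used for
localization; run-to-run agreement (pairwise correlation of PIB pixels)
is the stability diagnostic that distinguishes a converged classifier
from an unconverged one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter, gaussian_filter
from skimage.transform import resize as _sk_resize

from .netpos import NetPosModel

__all__ = [
    "AMSchedule",
    "PatternImageBlock",
    "am_inner_loop",
    "generate_pib",
    "mean_pib",
    "pib_stability_report",
]

_TARGETS = ("lesion", "normal")


@dataclass(frozen=True)
class AMSchedule:
    """Multi-scale activation-maximization schedule.

    Defaults are the method's stated settings: start at 7×7, 20 inner
    gradient steps, 8 outer rounds with upscale factor 1.2 and blur
    size 2.  ``eta`` is the normalized-gradient step in z-score units.
    ``blur`` selects the smoother: 'box' (2×2 uniform, reflect padding)
    or 'gaussian' (σ=1).
    """

    start_size: int = 7
    cnn_size: int = 28
    inner_iters: int = 20
    outer_iters: int = 8
    upscale_factor: float = 1.2
    blur_size: int = 2
    blur: str = "box"
    eta: float = 0.2
    final_reduce: str = "resize"  # 'resize' (phase-neutral) or 'crop'
    seed: int = 0

    def __post_init__(self):
        if min(self.start_size, self.cnn_size, self.inner_iters,
               self.outer_iters, self.blur_size) <= 0 or self.eta < 0 \
                or self.upscale_factor <= 0:
            raise ValueError("schedule sizes must be positive and eta >= 0")
        if self.start_size * self.upscale_factor ** self.outer_iters \
                < self.cnn_size - 3:
            raise ValueError("schedule never reaches the CNN input size")

    def size_sequence(self) -> list[int]:
        """Working-image sizes before each outer round (successive
        rounding), plus the final upscaled size."""
        sizes = [self.start_size]
        for _ in range(self.outer_iters):
            sizes.append(int(round(sizes[-1] * self.upscale_factor)))
        return sizes


@dataclass
class PatternImageBlock:
    """A 28×28 template x* in working-image intensity units.

    The template retains the (positive) mean of the optimized working
    image; when it is fed back to the classifier it is per-block
    z-scored first, as in every forward pass of the synthesis loop."""

    pixels: np.ndarray
    target: str
    final_activation: float
    run_seed: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (28, 28):
            raise ValueError("PIB must be 28×28")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")


def _zscore_block(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean, sd = float(x.mean()), float(x.std())
    if sd < 1e-12:
        sd = 1.0
    return (x - mean) / sd, mean, sd


def am_inner_loop(model: NetPosModel, working_image: np.ndarray, target: str,
                  schedule: AMSchedule) -> np.ndarray:
    """One inner AM round on the working image (any scale).

    Resize to 28×28, z-score, run ``inner_iters`` normalized gradient
    steps on the output logit (ascent for 'lesion', descent for
    'normal'), undo the z-score with the stored statistics and resize
    back to the working scale.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}")
    working_image = np.asarray(working_image, dtype=float)
    size = working_image.shape[0]
    cnn = schedule.cnn_size
    x = working_image if size == cnn else _sk_resize(
        working_image, (cnn, cnn), order=1, preserve_range=True,
        anti_aliasing=False)
    x, mean, sd = _zscore_block(x)
    sign = 1.0 if target == "lesion" else -1.0
    for _ in range(schedule.inner_iters):
        g = model.input_gradient(x)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during AM")
        gmax = np.abs(g).max()
        if gmax > 0:
            x = x + sign * schedule.eta * g / gmax
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite pixel during AM update")
    x = x * sd + mean
    if size != cnn:
        x = _sk_resize(x, (size, size), order=1, preserve_range=True,
                       anti_aliasing=False)
    return x


def _blur(x: np.ndarray, schedule: AMSchedule, round_idx: int = 0) -> np.ndarray:
    if schedule.blur == "box":
        # an even-sized box kernel is half-a-pixel off-center; alternate
        # its origin between rounds so repeated blurring does not drift
        # the pattern across the block
        origin = 0 if round_idx % 2 == 0 else -(schedule.blur_size - 1)
        return uniform_filter(x, size=schedule.blur_size, mode="reflect",
                              origin=origin)
    if schedule.blur == "gaussian":
        return gaussian_filter(x, sigma=1.0, mode="reflect")
    raise ValueError(f"unknown blur {schedule.blur!r}")


def generate_pib(model: NetPosModel, target: str,
                 schedule: AMSchedule | None = None, seed: int = 0,
                 *, strict: bool = True) -> PatternImageBlock:
    """Synthesize one PIB from seeded uniform noise.

    Runs the full multi-scale loop, then center-crops (or resizes) the
    final working image to 28×28 and z-scores it — PIBs live in the
    same normalized-intensity space as the images they are matched
    against.  A pure function of (model, schedule, seed).

    With ``strict=True`` a PIB whose final activation lands on the
    wrong side of 0.5 (a symptom of an untrained model) raises
    ``RuntimeError``.
    """
    schedule = schedule or AMSchedule()
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(schedule.start_size, schedule.start_size))
    for k in range(schedule.outer_iters):
        x = am_inner_loop(model, x, target, schedule)
        new_size = int(round(x.shape[0] * schedule.upscale_factor))
        x = _sk_resize(x, (new_size, new_size), order=1, preserve_range=True,
                       anti_aliasing=False)
        x = _blur(x, schedule, k)
    cnn = schedule.cnn_size
    if x.shape[0] > cnn and schedule.final_reduce == "crop":
        off = (x.shape[0] - cnn) // 2
        x = x[off:off + cnn, off:off + cnn]
    elif x.shape[0] != cnn:
        x = _sk_resize(x, (cnn, cnn), order=1, preserve_range=True,
                       anti_aliasing=False)
    # final refinement pass at the CNN scale: the last blur/reduce acts
    # after the last gradient update, so polish once more at 28×28 to
    # reach the stated endpoint (probability ≈ 1 for the lesion target)
    x = am_inner_loop(model, x, target, schedule)
    # the template stays in working (un-normalized) space — its positive
    # mean is what makes bright tissue respond in the convolution stage;
    # the classifier itself always consumes per-block z-scored input
    act = float(model.predict_proba(_zscore_block(x)[0])[0])
    wrong = act <= 0.5 if target == "lesion" else act >= 0.5
    if strict and wrong:
        raise RuntimeError(
            f"PIB rejected: final activation {act:.3f} on the wrong side of "
            f"0.5 for target {target!r} (model likely untrained)")
    return PatternImageBlock(x, target, act, int(seed))


def generate_pibs(model: NetPosModel, target: str, n_runs: int,
                  schedule: AMSchedule | None = None) -> list[PatternImageBlock]:
    """Collect ``n_runs`` *accepted* PIBs from derived seeds.

    Occasionally a run collapses (e.g. to a near-constant image) and
    lands on the wrong side of 0.5; such runs are rejected with a
    warning and replaced by the next derived seed, so the mean template
    is always built from valid runs.  Deterministic for a fixed
    schedule seed.
    """
    import warnings

    schedule = schedule or AMSchedule()
    accepted: list[PatternImageBlock] = []
    attempts = 0
    max_attempts = 3 * n_runs + 5
    while len(accepted) < n_runs and attempts < max_attempts:
        seed = int(np.random.SeedSequence(
            entropy=schedule.seed, spawn_key=(attempts,))
            .generate_state(1)[0] % 2 ** 31)
        attempts += 1
        pib = generate_pib(model, target, schedule, seed, strict=False)
        wrong = (pib.final_activation <= 0.5 if target == "lesion"
                 else pib.final_activation >= 0.5)
        if wrong:
            warnings.warn(
                f"rejected AM run (seed {seed}): activation "
                f"{pib.final_activation:.3f} on the wrong side of 0.5")
            continue
        accepted.append(pib)
    if len(accepted) < n_runs:
        raise RuntimeError(
            f"only {len(accepted)}/{n_runs} AM runs accepted after "
            f"{attempts} attempts; model likely untrained")
    return accepted


def mean_pib(pibs: list[PatternImageBlock],
             model: NetPosModel | None = None) -> PatternImageBlock:
    """Pixel-wise mean of ≥2 same-target PIBs; the activation is
    recomputed on the mean when a model is supplied."""
    if len(pibs) < 2:
        raise ValueError("mean_pib needs at least 2 runs")
    targets = {p.target for p in pibs}
    if len(targets) != 1:
        raise ValueError("cannot average PIBs with mixed targets")
    pixels = np.mean([p.pixels for p in pibs], axis=0)
    act = float(model.predict_proba(_zscore_block(pixels)[0])[0]) \
        if model is not None else float("nan")
    return PatternImageBlock(pixels, pibs[0].target, act, pibs[0].run_seed)


def _pairwise_correlations(pibs: list[PatternImageBlock]) -> list[float]:
    out = []
    for i in range(len(pibs)):
        for j in range(i + 1, len(pibs)):
            a, b = pibs[i].pixels.ravel(), pibs[j].pixels.ravel()
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return out


def pib_stability_report(model: NetPosModel, target: str, n_runs: int,
                         schedule: AMSchedule | None = None) -> dict:
    """Run AM ``n_runs`` times with derived seeds and summarize
    run-to-run agreement.

    Returns mean/min pairwise pixel correlation, per-run final
    activations, the runs themselves, and a ``stable`` verdict (mean
    correlation > 0.8 with every activation on the correct side of
    0.5).  An unconverged model typically shows correlations near 0.
    """
    if n_runs < 2:
        raise ValueError("stability report needs n_runs >= 2")
    schedule = schedule or AMSchedule()
    seeds = [int(np.random.SeedSequence(
        entropy=schedule.seed, spawn_key=(k,)).generate_state(1)[0] % 2 ** 31)
        for k in range(n_runs)]
    pibs = [generate_pib(model, target, schedule, s, strict=False)
            for s in seeds]
    corrs = _pairwise_correlations(pibs)
    acts = [p.final_activation for p in pibs]
    right_side = all(a > 0.5 if target == "lesion" else a < 0.5 for a in acts)
    n_wrong = sum(1 for a in acts
                  if (a <= 0.5 if target == "lesion" else a >= 0.5))
    return {
        "target": target,
        "n_runs": n_runs,
        "mean_correlation": float(np.mean(corrs)),
        "min_correlation": float(np.min(corrs)),
        "activations": acts,
        "n_wrong_side": n_wrong,
        "stable": bool(np.mean(corrs) > 0.8 and right_side),
        "pibs": pibs,
    }
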