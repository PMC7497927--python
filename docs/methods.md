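# Methods

## The model and its assumptions

The method rests on one premise: a subvisible cortical lesion, although
indistinguishable by eye from noise, is still the *strongest compact
hyperintense anomaly* in its image.  A small CNN trained to separate
lesion-centered from normal 28×28 blocks internalizes that pattern;
activation maximization (AM) then extracts it as an explicit template,
and plain cross-correlation with that template localizes lesions that
the classifier alone could not place (the classifier's firing radius is
only a few pixels, whereas the convolution scans every center).

The classifier ("Net-Pos") is LeNet-scale: conv 6@5×5 (pad 2) → ReLU →
2×2 maxpool → conv 16@5×5 → ReLU → 2×2 maxpool → dense 120 → ReLU →
dense 84 → ReLU → one sigmoid unit; feature maps run 6×28×28 → 6×14×14
→ 16×10×10 → 16×5×5 → 400.  Layer-wise counting gives 60 941 trainable
parameters (156 + 2 416 + 48 120 + 10 164 + 85).  ReLU after the dense
layers is our choice; only the convolutional activations are fixed by
the architecture description.  The loss is mean binary cross-entropy
with probabilities clamped to [1e−7, 1−1e−7]; the optimizer is
conventional SGD-with-momentum, `v ← ρv + g`, `θ ← θ − lr·v`
(lr = 0.01, ρ = 0.9).  A damped variant that *subtracts* the momentum
term is retained behind `TrainConfig.literal_momentum` for comparison
but is not the default, because it is not what "SGDM" names.

All network code is numpy (`amcl.nn`) with hand-written backward
passes, checked against central finite differences to < 1e−4 relative
error.  This gives direct access to the two derivative fields the
method needs — ∂logit/∂pixels for AM and ∂logit/∂(last conv maps) for
Grad-CAM — and keeps the whole artifact free of deep-learning framework
dependencies.

## Dataset construction

Images are bilinearly resampled to 256×256 and z-scored over the brain
mask (population variance; background pixels set to 0 — in-mask
statistics keep the large background from dominating).  The block
window centered at (r, c) spans rows r−13…r+14, matching the index
convention of the localization stage.  Positive blocks: every lesion
pixel is tried as a center and kept iff the window holds > 4/5·784
lesion pixels or ≥ 4/5 of the lesion's total pixels.  Negative blocks
are sampled (seeded, without replacement) in equal thirds from three
regions placed symmetrically about the image center: N1 is the point
reflection of the lesion bounding box dilated by 14 px; N2/N3 mirror N1
across the vertical/horizontal midlines.  A negative candidate is
rejected if its window *or the point reflection of its window* touches
the lesion.  Rotation augmentation runs the extraction on the image
rotated every 24° (bilinear for intensities, nearest-neighbor for
masks).  Keeping one negative per positive per rotated image holds the
class ratio at 1:1.

For desk-scale runs the number of positives kept per rotated image is
capped (default 20, sampled without replacement), giving ≈ 9 600 blocks
for the 16-image training class — enough for the task, which is
Bayes-separable at the positive-class contrast.

## Activation maximization

The working image starts as seeded uniform noise at 7×7.  Each of 8
outer rounds: resize to 28×28 (bilinear), z-score, take 20 gradient
steps on the *logit* of the output neuron (ascent for the lesion
target, descent for normal), undo the z-score, resize back, then
upscale by ×1.2 (successive rounding gives sizes
7→8→10→12→14→17→20→24→29) and apply a 2×2 box blur.  Numerical
choices that matter:

* **Step size.**  Steps are normalized, `x ← x ± η·g/max|g|`, with
  η = 0.2 in z-units.  At η = 0.1 the runs retain memory of their
  noise initialization (pairwise correlation ≈ 0.7); at η = 0.2 four
  independently seeded runs agree to correlation ≈ 0.98 while the
  endpoint activations are unchanged.
* **Blur phase.**  A 2×2 box kernel is half-a-pixel off-center; its
  origin alternates between rounds, otherwise eight applications drift
  the pattern ~4 px toward one corner and the template core ends up
  off-center.
* **Final reduction.**  29→28 by bilinear resize (phase-neutral); a
  corner-anchored crop is available via `AMSchedule.final_reduce`.
* **Final polish.**  One more 20-step pass at 28×28 after the last
  upscale, so the endpoint property — classifier probability ≈ 1 for
  the lesion template, ≈ 0 for the normal one — holds for every seed.
* **Objective.**  Gradients are taken on the pre-sigmoid logit (same
  argmax as the probability, no saturation); probabilities are only
  reported.

The template (pattern image block, PIB) is kept in the *working*
intensity space, not re-z-scored: the inner loop un-normalizes after
every round, so the synthesized template retains a positive mean.
That mean is load-bearing downstream: convolved with a z-scored image,
it makes bright cortical tissue respond positively, and the lesion's
extra response then rides on that baseline.  Thresholding at 0.9·max
consequently keeps a lesion-centered region of roughly lesion size
(the baseline "subsidizes" the cut), which is what produces Dice
scores commensurate with lesion area.  A zero-mean template instead
yields a needle-sharp response peak whose 0.9-level set is far smaller
than any lesion.  The classifier itself always consumes per-block
z-scored input, so this choice does not affect the endpoint
activations.  The localization template is the pixel-wise mean of four
runs; run-to-run pairwise correlation is the convergence diagnostic
(an untrained classifier produces uncorrelated, rejected templates).
A run whose endpoint lands on the wrong side of 0.5 — occasionally the
optimization collapses to a near-constant image — is rejected with a
warning and replaced from the derived seed stream, so the mean
template is always built from valid runs; the stability report, whose
job is to *detect* instability, keeps all runs and counts the
rejections.

## Localization and evaluation

`Iconv(i,j)` is the stride-1 sum of the element-wise product of the
28×28 window and the template — cross-correlation without kernel flip,
computed by FFT and verified against a double-loop oracle to < 1e−8.
Centers whose window does not fit are excluded from the response and
from its maximum.  The predicted mask keeps values ≥ 0.9·max (equality
retained; the threshold fraction can be re-derived on phantoms with
`threshold_sweep`).  Overlays follow the red = TP, green = FP,
blue = FN convention.

Metrics are pixel-wise over the full 256×256 frame (a config flag
restricts to the brain mask; the full frame is the default because the
published near-99 specificity values imply a large true-negative
pool).  Undefined ratios (zero denominator) are reported as missing,
excluded from averages with an exclusion count, never coerced to 0.
An image is *detected* when pixel recall > 20 (strict); subject-wise
recall is the percentage of lesion-bearing images detected, and pooled
tables average per image, unweighted.

Cross-validation is leave-one-patient-out over the visible-lesion
patients (the training class): each fold trains on the other patients'
blocks, synthesizes its own mean template, and localizes the held-out
patient's images.  Subvisible-lesion images are new data for every such
model, so they are evaluated once with a template from a model trained
on all visible-lesion patients.

## Grad-CAM comparator

For a block the classifier calls lesion (p > 0.5), channel weights are
the spatially averaged gradients of the logit with respect to the last
conv layer's 16×10×10 output (Z = 100), and the map is the
ReLU-rectified weighted sum.  The feature maps are taken at the conv
module's output, as a framework hook would capture them.  Image-level
assembly (unspecified in the method's description) is our convention:
blocks scanned at stride 4 — the classifier only fires within ~4 px of
a centered lesion, so a half-window stride can step entirely over one —
with firing blocks' maps bilinearly upsampled to 28×28, accumulated
under per-pixel coverage normalization, and binarized with the same
0.9·max rule as the template method.

On phantom-trained classifiers Grad-CAM is markedly unstable: for some
training seeds every α_k·A^k combination is negative over the whole
block and the ReLU zeroes the map — the classifier encodes lesion
evidence as local *contrast*, so its brightness-tracking channels carry
negative weights.  This is a known failure mode of gradient-averaged
CAMs and consistent with the comparator's weak published behaviour on
subvisible lesions; we report it rather than patch it, since the
comparator exists to be compared against.

## The phantom generator

Real FLAIR images of this patient population are not distributed, so
the generator emulates the statistical structure the method assumes:

* an elliptical brain (semi-axes ≈ 100×85 px at 256², ±10 % per
  patient) over a flat background, with a brighter cortical band whose
  *inner boundary undulates* (19 sinusoidal periods, 5 px amplitude) —
  a straight GM/WM interface at window scale would be anatomically
  wrong and would dominate the template response;
* intensity levels 0.50 (brain) / 0.58 (cortex) in arbitrary units,
  smoothed with a σ = 1.5 px point-spread blur (tissue interfaces in
  MR are partial-volume ramps, not step edges), plus i.i.d. Gaussian
  noise (SD 0.03) inside the brain;
* at most one disc lesion per image, flat core (70 % of its radius,
  matching the homogeneous appearance of lesional hyperintensity) with
  a Gaussian shoulder truncated at the support radius (5.5–7.5 px);
  the ground-truth mask is the half-maximum contour, the way a rater
  traces a blurred lesion.  Placement keeps a 4-px ring around the
  lesion on locally uniform cortex, so that with zero noise the
  core-minus-ring contrast equals the nominal contrast *exactly*, and
  keeps the point reflection of the lesion lesion-free;
* two contrast presets define the study conditions: positive = 8× and
  negative = 2× the noise SD (the subvisible regime the method
  targets);
* two diffuse bright distractor blobs (amplitude 0.02, σ = 6 px,
  ≥ 28 px from the lesion) model mild regional brightness variation
  and stress false-positive behaviour.

What the phantoms do **not** model: MR physics, gyral folding beyond a
sinusoidal boundary, partial-volume texture inside tissue classes,
multi-focal lesions, or inter-sequence intensity variation.  Passing
phantom tests therefore shows the pipeline implements the method
faithfully and recovers planted structure under its stated premise —
not that the method would reach the same scores on clinical data.

## Problem sizes and determinism

Default desk-scale sizes: 34 images (16 visible / 18 subvisible) from
19 synthetic patients; ≤ 20 positives per rotated image (15 rotations);
batch 64, ≤ 20 epochs with early stop when the epoch cost falls below
1e−3 or its relative improvement falls below 1e−3; 4 AM runs per
template, 5 for stability reports.  One pipeline run is a single-CPU,
few-minute computation.  Every stage draws its seed from the global
seed through named substreams, so runs are bit-reproducible and stages
are individually replayable.

## Known limitations

* 2D only; the natural 3D extension would need volumetric training
  data and is out of scope.
* No false-positive suppression or connected-component post-filtering:
  the predicted mask is exactly the 0.9·max super-level set.
* The 4/5 block rules make the positive set degenerate for lesions far
  larger than the window interior (rule 1 needs > 627 lesion pixels in
  a 784-pixel window); phantom lesions are sized well below that
  regime.
* Grad-CAM results depend strongly on the training seed (see above);
  the template method does not share this instability.
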