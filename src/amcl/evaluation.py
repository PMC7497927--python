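"""Segmentation metrics, subject-wise detection, and the LOOCV harness.

Pixel-wise confusion counts feed five scores, all on a 0–100 scale:

    Specificity = TN/(TN+FP)·100        Accuracy = (TP+TN)/total·100
    Recall      = TP/(TP+FN)·100        Precision = TP/(TP+FP)·100
    Dice        = 2·TP·100/(2·TP+FP+FN)

Ratios with a zero denominator are *undefined* (None), never silently
zero.  By default counts are taken over the full image frame; a region
mask restricts them.

An image counts as *detected* when its pixel recall exceeds 20 (strict
inequality); subject-wise recall is the percentage of lesion-bearing
images detected.

Because the classifier is trained only on visible-lesion patients,
cross-validation is leave-one-patient-out over those patients: each
fold trains on the remaining visible-lesion patients' blocks,
synthesizes the mean lesion template, and localizes the held-out
patient's images.  Subvisible-lesion images are new data for every such
model, so they are evaluated once with a template from a model trained
on all visible-lesion patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import netpos, preprocess
from .activation_max import AMSchedule, generate_pibs, mean_pib
from .gradcam import gradcam_localize
from .localization import template_response, threshold_response

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "metrics",
    "subject_wise_recall",
    "LoocvConfig",
    "loocv_evaluate",
]

DETECTION_RECALL = 20.0  # pixel-recall threshold for a subject-wise hit

METRIC_NAMES = ("specificity", "accuracy", "recall", "precision", "dice")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five scores on the 0–100 scale; None marks an undefined
    ratio (zero denominator)."""

    specificity: float | None
    accuracy: float | None
    recall: float | None
    precision: float | None
    dice: float | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def confusion(pred, truth, region=None) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against truth,
    over the whole frame or a region mask."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("pred and truth shape mismatch")
    if region is not None:
        r = np.asarray(region).astype(bool)
        if r.shape != p.shape:
            raise ValueError("region shape mismatch")
        p, t = p[r], t[r]
    return ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                           tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five scores from confusion counts (×100 scale)."""
    if c.total == 0:
        raise ValueError("no evaluated pixels")
    return MetricSet(
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        recall=_ratio(c.tp, c.tp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def subject_wise_recall(reports: list[MetricSet]) -> float:
    """Percent of images detected, detection = pixel recall > 20.

    Images whose recall is undefined (no lesion truth) are excluded
    with a warning — every evaluated image is expected to carry a
    lesion.
    """
    considered = [r for r in reports if r.recall is not None]
    n_excluded = len(reports) - len(considered)
    if n_excluded:
        warnings.warn(f"{n_excluded} image(s) without lesion truth excluded "
                      "from subject-wise recall")
    if not considered:
        raise ValueError("no images with lesion truth")
    detected = sum(1 for r in considered if r.recall > DETECTION_RECALL)
    return 100.0 * detected / len(considered)


# ---------------------------------------------------------------------
# LOOCV harness
# ---------------------------------------------------------------------

@dataclass
class LoocvConfig:
    """Everything one cross-validated evaluation run needs."""

    train: netpos.TrainConfig = field(default_factory=netpos.TrainConfig)
    schedule: AMSchedule = field(default_factory=AMSchedule)
    target_grid: int = 256
    rotation_step: float = 24.0
    max_pos_per_rotation: int | None = None
    n_am_runs: int = 4
    threshold_frac: float = 0.9
    include_gradcam: bool = True
    evaluate_in_brain: bool = False  # restrict pixel metrics to the brain
    seed: int = 0


def _evaluate_image(image, lesion, pib, model, cfg: LoocvConfig) -> dict:
    """Normalize one image, run both localizers, return metric records."""
    img_r, les_r = preprocess.resize_to_grid(image, cfg.target_grid, lesion)
    img_n = preprocess.zscore_normalize(img_r)
    rec = {"image_id": image.image_id, "patient_id": image.patient_id,
           "contrast_class": image.contrast_class}
    region = img_n.brain_mask if cfg.evaluate_in_brain else None

    resp = template_response(img_n, pib)
    loc = threshold_response(resp, cfg.threshold_frac)
    rec["amcl"] = metrics(confusion(loc.predicted_mask, les_r.mask, region))
    rec["amcl_max_response"] = loc.max_response

    if cfg.include_gradcam:
        gloc = gradcam_localize(model, img_n, frac=cfg.threshold_frac)
        rec["gradcam"] = metrics(confusion(gloc.predicted_mask, les_r.mask,
                                           region))
    return rec


def _fold_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=base, spawn_key=(k,))
               .generate_state(1)[0] % 2 ** 31)


def _train_and_template(dataset, cfg: LoocvConfig, fold_seed: int):
    """Train a fold model and distill its mean lesion template."""
    import dataclasses as _dc

    tconf = _dc.replace(cfg.train, seed=fold_seed)
    model, history = netpos.fit_blocks(dataset, tconf)
    sched = _dc.replace(cfg.schedule, seed=fold_seed)
    pibs = generate_pibs(model, "lesion", cfg.n_am_runs, sched)
    return model, mean_pib(pibs, model), history


def _pool(records: list[dict], algorithm: str) -> dict:
    """Unweighted per-image means of each defined metric plus the
    subject-wise recall, for one algorithm over one image list."""
    sets = [r[algorithm] for r in records]
    pooled: dict = {"subject_wise_recall": subject_wise_recall(sets)}
    for name in METRIC_NAMES:
        vals = [getattr(s, name) for s in sets]
        defined = [v for v in vals if v is not None]
        pooled[name] = float(np.mean(defined)) if defined else None
        pooled[f"n_undefined_{name}"] = len(vals) - len(defined)
    pooled["n_images"] = len(records)
    return pooled


def loocv_evaluate(cohort, config: LoocvConfig | None = None) -> dict:
    """Leave-one-patient-out evaluation of both localizers on a cohort.

    Returns ``{"folds": [...], "per_image": [...], "pooled":
    {algorithm: {class: summary}}}``; the pooled table carries the
    subject-wise recall and the five pixel metrics per algorithm and
    contrast class.
    """
    cfg = config or LoocvConfig()
    positive = [(i, l) for i, l in cohort if i.contrast_class == "positive"]
    negative = [(i, l) for i, l in cohort if i.contrast_class == "negative"]
    pos_patients = sorted({i.patient_id for i, _ in positive})
    if len(pos_patients) < 3:
        raise ValueError("LOOCV needs at least 3 positive-class patients")

    dataset = preprocess.build_dataset(
        positive, "positive_only", target=cfg.target_grid,
        rotation_step=cfg.rotation_step,
        max_pos_per_rotation=cfg.max_pos_per_rotation, seed=cfg.seed)

    folds, per_image = [], []
    for k, held_out in enumerate(pos_patients):
        train_pids = [p for p in pos_patients if p != held_out]
        sub = dataset.subset(train_pids)
        if sub.counts[1] == 0:
            warnings.warn(f"fold {held_out}: no positive blocks, skipped")
            continue
        model, pib, history = _train_and_template(sub, cfg, _fold_seed(cfg.seed, k))
        fold_records = [_evaluate_image(img, les, pib, model, cfg)
                        for img, les in positive if img.patient_id == held_out]
        per_image.extend(fold_records)
        folds.append({"held_out": held_out, "train_patients": train_pids,
                      "n_train_blocks": len(sub), "final_cost": history[-1],
                      "pib_activation": pib.final_activation,
                      "n_images": len(fold_records)})

    # negative-class images: one model trained on every positive patient
    full_model, full_pib, history = _train_and_template(
        dataset, cfg, _fold_seed(cfg.seed, len(pos_patients)))
    neg_records = [_evaluate_image(img, les, full_pib, full_model, cfg)
                   for img, les in negative]
    per_image.extend(neg_records)
    folds.append({"held_out": None, "train_patients": pos_patients,
                  "n_train_blocks": len(dataset), "final_cost": history[-1],
                  "pib_activation": full_pib.final_activation,
                  "n_images": len(neg_records)})

    algorithms = ["amcl"] + (["gradcam"] if cfg.include_gradcam else [])
    pooled = {}
    for algo in algorithms:
        pooled[algo] = {}
        for cls in ("positive", "negative"):
            recs = [r for r in per_image if r["contrast_class"] == cls]
            if recs:
                pooled[algo][cls] = _pool(recs, algo)
    return {"folds": folds, "per_image": per_image, "pooled": pooled,
            "models": {"full": full_model, "full_pib": full_pib}}
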