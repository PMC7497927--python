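"""End-to-end reproducible pipeline: generate → extract → train → PIB →
localize → Grad-CAM → evaluate.

A single :class:`RunConfig` (YAML-serializable) drives every stage; the
global seed fans out into per-stage seeds through named substreams, so
each stage is individually reproducible and two runs of one config are
identical.  Every artifact is written under the output directory with a
provenance record (config, derived seeds, package versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import netpos, phantom, preprocess
from .activation_max import (AMSchedule, generate_pibs, mean_pib,
                             pib_stability_report)
from .evaluation import LoocvConfig, loocv_evaluate
from .gradcam import gradcam_localize
from .localization import make_overlay, template_response, threshold_response

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("amcl")

#: stage names with fixed substream indices
_STAGES = ("phantom", "blocks", "train", "pib", "localize", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
               .generate_state(1)[0] % 2 ** 31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    phantom: phantom.PhantomParams = field(default_factory=phantom.PhantomParams)
    train: netpos.TrainConfig = field(default_factory=netpos.TrainConfig)
    schedule: AMSchedule = field(default_factory=AMSchedule)
    target_grid: int = 256
    rotation_step: float = 24.0
    max_pos_per_rotation: int | None = 20
    contrast_filter: str = "positive_only"
    n_am_runs: int = 4
    threshold_frac: float = 0.9
    include_gradcam: bool = True
    image_format: str = "nii"
    seed: int = 0
    outdir: str = "amcl_run"

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("brain_axes", "lesion_radius_range"):
                if ph.get(key) is not None:
                    ph[key] = tuple(ph[key])
            d["phantom"] = phantom.PhantomParams(**ph)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = netpos.TrainConfig(**d["train"])
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = AMSchedule(**d["schedule"])
        return cls(**d)

    def loocv_config(self) -> LoocvConfig:
        return LoocvConfig(
            train=dataclasses.replace(self.train,
                                      seed=stage_seed(self.seed, "train")),
            schedule=dataclasses.replace(self.schedule,
                                         seed=stage_seed(self.seed, "pib")),
            target_grid=self.target_grid,
            rotation_step=self.rotation_step,
            max_pos_per_rotation=self.max_pos_per_rotation,
            n_am_runs=self.n_am_runs,
            threshold_frac=self.threshold_frac,
            include_gradcam=self.include_gradcam,
            seed=stage_seed(self.seed, "evaluate"),
        )


def _metricset_to_jsonable(obj):
    from .evaluation import MetricSet

    if isinstance(obj, MetricSet):
        return obj.as_dict()
    if isinstance(obj, dict):
        return {k: _metricset_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_metricset_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts under ``config.outdir``.

    Returns the run report (also written as ``report.json``): the
    training report of the full model, the PIB stability summary, and
    the pooled cross-validated metric table per algorithm and contrast
    class.  Deterministic for a fixed config.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.to_yaml(out / "config.yaml")
    log.info("run parameters: lr=%g momentum=%g rotation_step=%g°, block "
             "rules 4/5, AM %d×%d iters from %d px, upscale ×%g blur %d, "
             "threshold %g·max, detection recall > 20",
             config.train.lr, config.train.momentum, config.rotation_step,
             config.schedule.outer_iters, config.schedule.inner_iters,
             config.schedule.start_size, config.schedule.upscale_factor,
             config.schedule.blur_size, config.threshold_frac)

    # 1. cohort ---------------------------------------------------------
    log.info("stage 1/6: generating phantom cohort")
    cohort = phantom.make_reference_cohort(config.phantom,
                                           stage_seed(config.seed, "phantom"))
    data_dir = out / "data"
    manifest = phantom.write_cohort(cohort, data_dir, fmt=config.image_format)

    # 2. blocks ---------------------------------------------------------
    log.info("stage 2/6: extracting 28×28 blocks")
    dataset = preprocess.build_dataset(
        cohort, config.contrast_filter, target=config.target_grid,
        rotation_step=config.rotation_step,
        max_pos_per_rotation=config.max_pos_per_rotation,
        seed=stage_seed(config.seed, "blocks"))
    _write_block_index(dataset, out / "blocks.csv")

    # 3. train ----------------------------------------------------------
    log.info("stage 3/6: training patch classifier on %d blocks", len(dataset))
    tconf = dataclasses.replace(config.train,
                                seed=stage_seed(config.seed, "train"))
    model = netpos.build_model(seed=tconf.seed)
    model, history, train_report = netpos.train(model, dataset, tconf)
    netpos.save_checkpoint(model, out / "checkpoint.npz")

    # 4. PIBs -----------------------------------------------------------
    log.info("stage 4/6: synthesizing pattern image blocks")
    sched = dataclasses.replace(config.schedule,
                                seed=stage_seed(config.seed, "pib"))
    stability = pib_stability_report(model, "lesion", config.n_am_runs, sched)
    runs = generate_pibs(model, "lesion", config.n_am_runs, sched)
    pib = mean_pib(runs, model)
    np.savez(out / "pibs.npz", mean=pib.pixels,
             **{f"run{i}": p.pixels for i, p in enumerate(runs)})
    _save_png(out / "pib_mean.png", pib.pixels)

    # 5 & 6. localize + Grad-CAM with the full model --------------------
    log.info("stage 5/6: localizing %d images", len(cohort))
    loc_dir = out / "localization"
    loc_dir.mkdir(exist_ok=True)
    per_image = []
    for image, lesion in cohort:
        img_r, les_r = preprocess.resize_to_grid(image, config.target_grid,
                                                 lesion)
        img_n = preprocess.zscore_normalize(img_r)
        resp = template_response(img_n, pib)
        res = threshold_response(resp, config.threshold_frac)
        overlay = make_overlay(img_n, les_r, res.predicted_mask)
        _save_png(loc_dir / f"{image.image_id}_overlay.png", overlay)
        np.savez(loc_dir / f"{image.image_id}_response.npz",
                 iconv=resp.iconv, predicted=res.predicted_mask)
        rec = {"image_id": image.image_id,
               "contrast_class": image.contrast_class,
               "threshold": res.threshold_used,
               "max_response": res.max_response,
               "detected_area": int(res.predicted_mask.sum())}
        if config.include_gradcam:
            gres = gradcam_localize(model, img_n, frac=config.threshold_frac)
            _save_png(loc_dir / f"{image.image_id}_gradcam.png",
                      make_overlay(img_n, les_r, gres.predicted_mask))
            rec["gradcam_area"] = int(gres.predicted_mask.sum())
        per_image.append(rec)

    # 7. pooled evaluation (patient-wise cross-validation) --------------
    log.info("stage 6/6: cross-validated evaluation")
    result = loocv_evaluate(cohort, config.loocv_config())

    report = {
        "config": asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "n_images": len(cohort),
        "n_blocks": len(dataset),
        "parameter_count": model.parameter_count,
        "train_report": train_report,
        "pib_stability": {k: v for k, v in stability.items() if k != "pibs"},
        "per_image": per_image,
        "pooled": _metricset_to_jsonable(result["pooled"]),
        "manifest": str(manifest),
        "runtime_s": time.time() - t0,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_metricset_to_jsonable(report), fh, indent=2, default=str)
    log.info("pipeline finished in %.1f s", report["runtime_s"])
    return report


def _write_block_index(dataset: preprocess.BlockDataset, path) -> None:
    import pandas as pd

    rows = [dict(block_id=i, label=b.label, patient_id=b.patient_id,
                 image_id=b.source_image_id, center_row=b.center[0],
                 center_col=b.center[1], angle=b.angle)
            for i, b in enumerate(dataset.blocks)]
    pd.DataFrame(rows).to_csv(path, index=False)


def _save_png(path, array: np.ndarray) -> None:
    import imageio.v3 as iio

    a = np.asarray(array, dtype=float)
    lo, hi = a.min(), a.max()
    scaled = (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)
    iio.imwrite(path, (scaled * 255).astype(np.uint8))
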