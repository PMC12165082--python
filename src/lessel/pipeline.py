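"""End-to-end orchestration: synthetic cohort -> models -> diagnosis.

:func:`run_end_to_end` exercises both arms at demo scale and writes every
artifact plus a manifest recording seeds, thresholds, per-stage counts and
file checksums, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import cna, config, diagnosis, imaging, synthdata

log = logging.getLogger("lessel.pipeline")


def train_all_models(
    seed: int = 0,
    n_detector_slides: int = 8,
    cells_per_slide: int = 10,
    n_qc_per_category: int = 30,
    n_seg_crops: int = 60,
    n_channel_cells: tuple[int, int] = (120, 220),
) -> imaging.SlideModels:
    """Train the full imaging cascade on freshly rendered synthetic data."""
    rng = np.random.default_rng(seed)
    # detector: annotated patches with all object kinds
    patches, gt = [], []
    for _ in range(n_detector_slides):
        spec = synthdata.SyntheticSlideSpec(
            n_cells=cells_per_slide, true_etc_fraction=20.0,
            junk_fraction=0.3, seed=int(rng.integers(2 ** 31)))
        wsi, ann = synthdata.render_slide(spec)
        patches.append(wsi)
        gt.append([imaging.BBox(*a["bbox"]) for a in ann])
    detector = imaging.train_detector(patches, gt, imaging.TrainConfig(seed=seed))

    crops, labels = synthdata.qc_training_set(n_qc_per_category, seed=seed + 1)
    qc = imaging.train_qc(crops, labels, imaging.TrainConfig(seed=seed))

    seg_crops, seg_masks = [], []
    srng = np.random.default_rng(seed + 2)
    for k in range(n_seg_crops):
        label = ("benign", "malignant")[k % 2]
        img, mask = synthdata.render_object(label, int(srng.integers(2 ** 31)))
        c, m = synthdata.object_crop(img, mask, margin=2)
        seg_crops.append(c)
        seg_masks.append(m)
    segmenter = imaging.train_segmenter(seg_crops, seg_masks,
                                        imaging.TrainConfig(seed=seed))

    models = {}
    for offset, channel in ((3, "large"), (4, "small")):
        cells, y = synthdata.channel_training_set(
            *n_channel_cells, size_class=channel, seed=seed + offset)
        models[channel] = imaging.train_channel_classifier(
            cells, y, channel, imaging.TrainConfig(seed=seed))
    return imaging.SlideModels(detector, qc, segmenter,
                               models["large"], models["small"])


def save_models(models: imaging.SlideModels, path: str | Path) -> None:
    joblib.dump(models, Path(path))


def load_models(path: str | Path) -> imaging.SlideModels:
    return joblib.load(Path(path))


def run_cna_demo(cfg: config.RunConfig, out: Path) -> dict:
    """Small clonal-vs-normal experiment through the whole CNA engine."""
    bins = synthdata.reference_bins(n_chroms=3, chrom_length=50_000_000,
                                    seed=cfg.seed + 11)
    clone = synthdata.CloneSpec(events=((0, 20, 70, 3), (1, 10, 55, 1)))
    profiles = []
    for i in range(12):
        is_clone = i < 6
        noise = synthdata.NoiseSpec(gc_bias=(1.0, -1.2, 1.4), overdispersion=0.01,
                                    target_mapd=0.3, seed=cfg.seed * 1000 + i)
        counts = synthdata.simulate_cell_counts(
            clone if is_clone else None, bins, noise,
            cell_id=f"{'tumor' if is_clone else 'normal'}_{i}")
        corrected = cna.gc_normalize(counts, bins, cfg.lowess_frac)
        track = cna.to_ratios(corrected, bins, counts.cell_id)
        profile = cna.segment_cbs(track, bins, cfg.cbs_alpha, cfg.cbs_undo_sd,
                                  cfg.cbs_max_perm, seed=cfg.seed + i)
        profiles.append(cna.call_states(profile, cfg.gain_log2, cfg.loss_log2))
    result = cna.call_malignant(profiles, len(bins), cfg.concordance_min,
                                cfg.min_cluster)
    cna.write_qc_report(profiles, out / "cna_qc_report.csv")
    cna.write_concordance(result, out / "cna_concordance.csv")
    calls = cna.write_calls(result, out / "cna_calls.csv")
    n_true = sum(1 for p in profiles if p.cell_id.startswith("tumor"))
    tp = sum(1 for cid in result.malignant_ids if cid.startswith("tumor"))
    fp = len(result.malignant_ids) - tp
    return {"n_cells": len(profiles), "n_tumor_truth": n_true,
            "n_called_malignant": len(result.malignant_ids),
            "tp": tp, "fp": fp,
            "mean_burden_tumor": float(np.mean(
                [p.burden for p in profiles if p.cell_id.startswith("tumor")]))}


def run_end_to_end(cfg: config.RunConfig, out_dir: str | Path) -> dict:
    """Run both arms end to end at demo scale; returns the manifest."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    manifest["stages"]["cna"] = run_cna_demo(cfg, out)

    models = train_all_models(seed=cfg.seed, n_detector_slides=6,
                              n_qc_per_category=20, n_seg_crops=40,
                              n_channel_cells=(80, 150))
    save_models(models, out / "models.joblib")
    manifest["stages"]["training"] = {
        "detector_validation_recall": models.detector.validation_recall,
        "detector_fg_threshold": models.detector.fg_threshold,
        "qc_validation_accuracy": models.qc.validation_accuracy,
        "segmenter_validation_dice": models.segmenter.validation_dice,
        "clf_large_threshold": models.clf_large.threshold,
        "clf_small_threshold": models.clf_small.threshold,
        "clf_large_test_auc": models.clf_large.test_auc,
        "clf_small_test_auc": models.clf_small.test_auc,
    }

    spec = synthdata.SyntheticSlideSpec(n_cells=20, true_etc_fraction=20.0,
                                        patch_grid=(1, 2), junk_fraction=0.2,
                                        seed=cfg.seed + 99)
    wsi, ann = synthdata.render_slide(spec)
    synthdata.save_slide(wsi, ann, out / "demo_slide.png", out / "demo_slide.json")
    slide, records, counts = imaging.run_slide(wsi, models, "demo", cfg)
    pd.DataFrame([{
        "slide": "demo", "patch": r.patch_index,
        "x": r.box.x, "y": r.box.y, "w": r.box.w, "h": r.box.h,
        "qc": r.qc.category, "channel": r.channel,
        "score": r.score, "call": r.call,
    } for r in records]).to_csv(out / "demo_cells.csv", index=False)
    (out / "demo_slide_result.json").write_text(json.dumps(
        dataclasses.asdict(slide), indent=2))
    manifest["stages"]["slide"] = {**counts,
                                   "etc_percent": slide.etc_percent,
                                   "call": bool(slide.call)}

    cohort = synthdata.simulate_cohort(40, 30, seed=cfg.seed + 7)
    cohort["call"] = cohort["etc_percent"] >= cfg.etc_cutoff_pct
    cohort.to_csv(out / "cohort.csv", index=False)
    report = diagnosis.cohort_report(cohort, cfg.ci_method)
    diagnosis.metrics_to_frame(report["model_metrics"]).to_csv(
        out / "cohort_metrics.csv", index=False)
    m = report["model_metrics"]
    manifest["stages"]["diagnosis"] = {
        "n_patients": report["n_patients"],
        "sensitivity": m.sensitivity.value,
        "specificity": m.specificity.value,
        "positive_increase_pct": report.get("positive_increase_pct"),
    }

    manifest["runtime_s"] = round(time.time() - t0, 1)
    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "models.joblib")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
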