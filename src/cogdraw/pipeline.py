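"""End-to-end experiment orchestration.

``run_experiment`` executes generate-or-load -> split -> train -> evaluate
-> explain -> IoU scoring and writes every artifact (split CSV, checkpoint,
training history, metrics JSON, heat-map text grids + PNG overlays, IoU
curves) under one run directory, stamped with the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import RunConfig
from .data import load_manifest, records_to_arrays, stratified_split
from .estimators import ConvAttClassifier, PoolingBaselineClassifier
from .evaluate import (classification_metrics, iou_curve, rollout_vs_permuted,
                       whole_drawing_roi)
from .explain import grad_cam, rollout_heatmaps
from .labels import hard_label
from .synthetic import TASKS, generate_cohort

log = logging.getLogger("cogdraw")

__all__ = ["run_experiment", "build_estimator", "ABLATION_GRID"]

#: (variant, inputs, label_mode) rows of the standard ablation comparison:
#: three single-input pooling baselines, the multi-input pooling baseline,
#: three single-input attention models, the multi-input attention model,
#: and the proposed multi-input attention model with soft labels.
ABLATION_GRID = [
    ("pooling_baseline", ("clock",), "hard"),
    ("pooling_baseline", ("cube",), "hard"),
    ("pooling_baseline", ("trail",), "hard"),
    ("pooling_baseline", TASKS, "hard"),
    ("conv_att", ("clock",), "hard"),
    ("conv_att", ("cube",), "hard"),
    ("conv_att", ("trail",), "hard"),
    ("conv_att", TASKS, "hard"),
    ("conv_att", TASKS, "soft"),
]


def build_estimator(cfg: RunConfig):
    """Instantiate the configured model variant from a run config."""
    common = dict(
        tasks=tuple(cfg.model.inputs), backbone=cfg.model.backbone,
        image_size=cfg.data.canvas_size, label_mode=cfg.label.mode,
        cutoff=cfg.label.cutoff, center=cfg.label.center,
        learning_rate=cfg.training.learning_rate, beta1=cfg.training.beta1,
        beta2=cfg.training.beta2, epsilon=cfg.training.epsilon,
        epochs=cfg.training.epochs, batch_size=cfg.training.batch_size,
        augment=cfg.training.augment,
        checkpoint_selection=cfg.training.checkpoint_selection,
        random_state=cfg.stage_seed("train"))
    if cfg.model.variant == "conv_att":
        return ConvAttClassifier(n_layers=cfg.model.n_layers,
                                 hidden_dim=cfg.model.hidden_dim,
                                 ffn_dim=cfg.model.ffn_dim, **common)
    if cfg.model.variant == "pooling_baseline":
        return PoolingBaselineClassifier(**common)
    raise ValueError(f"unknown model variant {cfg.model.variant!r}")


def _save_heatmap(path_stem: Path, hm: np.ndarray) -> None:
    np.savetxt(path_stem.with_suffix(".txt"), hm, fmt="%.6e")
    lo, hi = hm.min(), hm.max()
    norm = (hm - lo) / (hi - lo) if hi > lo else np.zeros_like(hm)
    Image.fromarray((255 * norm).astype(np.uint8)).save(
        path_stem.with_suffix(".png"))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a manifest of produced artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    artifacts: dict[str, str] = {}

    # generate or load -----------------------------------------------------
    @_stage("generate")
    def _data():
        if cfg.data.manifest:
            return load_manifest(cfg.data.manifest)
        cohort_dir = out / "cohort"
        generate_cohort(cfg.data.n_subjects,
                        severity_distribution=cfg.data.severity_distribution,
                        out_dir=cohort_dir, rng_seed=cfg.stage_seed("generate"),
                        canvas_size=cfg.data.canvas_size,
                        noise_sd=cfg.data.noise_sd)
        artifacts["cohort_manifest"] = str(cohort_dir / "manifest.csv")
        return load_manifest(cohort_dir / "manifest.csv")

    records = _data()

    # split ----------------------------------------------------------------
    @_stage("split")
    def _split():
        split = stratified_split(records, fractions=cfg.evaluate.fractions,
                                 seed=cfg.stage_seed("split"),
                                 cutoff=cfg.label.cutoff)
        split.to_frame().to_csv(out / "split.csv", index=False)
        artifacts["split"] = str(out / "split.csv")
        return split

    split = _split()
    X, y = records_to_arrays(records, size=cfg.data.canvas_size)
    part = np.array([split.assignment[r.subject_id] for r in records])
    tr, va, te = (part == "train"), (part == "validation"), (part == "test")

    # train ----------------------------------------------------------------
    @_stage("train")
    def _train():
        est = build_estimator(cfg)
        est.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        est.history_.to_csv(out / "history.csv", index=False)
        est.save(out / "checkpoint")
        artifacts["history"] = str(out / "history.csv")
        artifacts["checkpoint"] = str(out / "checkpoint.npz")
        return est

    est = _train()

    # evaluate -------------------------------------------------------------
    @_stage("evaluate")
    def _evaluate():
        p = est.predict_proba(X[te])[:, 1]
        truth = np.asarray(hard_label(y[te], cutoff=cfg.label.cutoff))
        acc, f1, auc = classification_metrics(p, truth)
        metrics = {"accuracy": acc, "f1": f1, "auc": auc,
                   "n_test": int(te.sum()), **stamp}
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        artifacts["metrics"] = str(out / "metrics.json")
        return metrics

    metrics = _evaluate()

    # explain --------------------------------------------------------------
    @_stage("explain")
    def _explain():
        hm_dir = out / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        if cfg.explain.method == "rollout":
            maps = rollout_heatmaps(est, X[te])
        elif cfg.explain.method == "gradcam":
            maps = grad_cam(est, X[te])
        else:
            raise ValueError(f"unknown explain method {cfg.explain.method!r}")
        test_ids = [r.subject_id for r, m in zip(records, te) if m]
        for task in maps:
            for i, sid in enumerate(test_ids):
                _save_heatmap(hm_dir / f"{sid}_{task}", maps[task][i])
        artifacts["heatmaps"] = str(hm_dir)
        return maps

    maps = _explain()

    # IoU scoring ----------------------------------------------------------
    @_stage("evaluate")
    def _iou():
        test_records = [r for r, m in zip(records, te) if m]
        heatmaps, whole_rois, expert_rois = [], [], []
        for i, rec in enumerate(test_records):
            imgs = X[np.flatnonzero(te)[i]]
            for t, task in enumerate(est.tasks):
                hm = maps[task][i]
                heatmaps.append(hm)
                ink_img = 1.0 - imgs[t, 0]      # back to white-background
                whole_rois.append(whole_drawing_roi(
                    ink_img, shape_kind=cfg.evaluate.roi_shape,
                    margin_px=cfg.evaluate.roi_margin_px,
                    ink_threshold=cfg.evaluate.ink_threshold))
                if task in rec.mask_paths:
                    mask = np.asarray(Image.open(rec.mask_paths[task])) > 127
                    expert_rois.append(mask)
                else:
                    expert_rois.append(None)
        curves = []
        whole = iou_curve(heatmaps, whole_rois, cfg.evaluate.k_values)
        whole["roi_type"] = "whole_drawing"
        curves.append(whole)
        paired = [(h, m) for h, m in zip(heatmaps, expert_rois)
                  if m is not None and m.any()]
        result = {}
        if paired:
            expert = iou_curve([h for h, _ in paired], [m for _, m in paired],
                               cfg.evaluate.k_values)
            expert["roi_type"] = "expert"
            curves.append(expert)
            result = rollout_vs_permuted(
                [h for h, _ in paired], [m for _, m in paired],
                k_percent=cfg.explain.top_k,
                rng=np.random.default_rng(cfg.stage_seed("explain")),
                grid_shape=est.grid_shape_)
        table = pd.concat(curves, ignore_index=True)
        table["method"] = cfg.explain.method
        table.to_csv(out / "iou_curves.csv", index=False)
        artifacts["iou_curves"] = str(out / "iou_curves.csv")
        return result

    localization = _iou()

    manifest = {**stamp, "artifacts": artifacts, "metrics": metrics,
                "localization": localization}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
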