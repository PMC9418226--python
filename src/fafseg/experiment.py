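"""End-to-end experiment runner tying the pipeline stages together.

Two modes mirror the dual pipelines of the study design:

* ``segment_t0`` -- baseline lesion segmentation; both the plain and the
  attention-gated network are trained per fold and compared.
* ``predict_t12`` -- progression prediction; the misaligned follow-up
  labels are first registered into the baseline frame, then the
  attention-gated network is trained on baseline images with Month-12
  labels as targets.

Every run emits per-image metric tables, a summary table (and a
comparison table when two models are trained), predicted masks,
heatmaps, the fold plan, per-epoch histories, and a manifest recording
every seed and hyperparameter so the run can be repeated bit-for-bit in
single-threaded execution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .crossval import FoldPlan, make_fold_plan, validate_subject_table
from .estimator import AttentionUNetSegmenter
from .metrics import comparison_table, evaluate_pair, summarize_metrics
from .preprocessing import standardize
from .registration import image_center, register_pair, warp_mask
from .visualization import attention_heatmap, deconv_reconstruct, save_heatmap_png

__all__ = ["ExperimentConfig", "run_experiment", "scan_scene_dir"]

VALID_MODES = ("segment_t0", "predict_t12")


@dataclass
class ExperimentConfig:
    mode: str = "segment_t0"
    scene_dir: str | None = None          # directory of saved synthetic scenes
    table: str | None = None              # or an explicit subject-table CSV
    out_dir: str = "fafseg_run"
    input_size: int = 64
    n_folds: int = 8
    n_validation: int = 0
    depth: int = 3
    base_filters: int = 8
    temperature: float = 1.0
    loss: str = "bce"
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    heatmaps: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.scene_dir is None and self.table is None:
            raise ValueError("config needs either scene_dir or table")
        for p in (self.scene_dir, self.table):
            if p is not None and not Path(p).exists():
                raise ValueError(f"configured path does not exist: {p}")
        if self.input_size % 2**self.depth:
            raise ValueError("input_size must be divisible by 2^depth")


def scan_scene_dir(scene_dir) -> pd.DataFrame:
    """Build a subject table from a directory of saved synthetic scenes."""
    scene_dir = Path(scene_dir)
    rows = []
    for sidecar in sorted(scene_dir.glob("*.json")):
        with open(sidecar) as fh:
            meta = json.load(fh)
        files = meta["files"]
        stem = sidecar.stem
        rows.append(
            {
                "sample_id": stem,
                "subject_id": stem,
                "eye": "right",
                "image": files["image_t0"],
                "mask_t0": files["mask_t0"],
                "mask_t12_moved": files.get("mask_t12_moved"),
                "image_t12_moved": files.get("image_t12_moved"),
                "mask_t12_true": files.get("mask_t12"),
            }
        )
    if not rows:
        raise ValueError(f"no scene sidecars (*.json) found in {scene_dir}")
    return pd.DataFrame(rows)


def _content_hash(table: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for path in sorted(table["image"]):
        h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured experiment; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        table = (
            scan_scene_dir(config.scene_dir)
            if config.scene_dir is not None
            else pd.read_csv(config.table)
        )
        validate_subject_table(table)

        stage = "preprocess"
        images, masks_t0 = {}, {}
        for _, row in table.iterrows():
            img, m = fio.read_sample(row["image"], row["mask_t0"])
            img, m = standardize(img, m, target_size=config.input_size)
            images[row["sample_id"]], masks_t0[row["sample_id"]] = img, m

        labels = dict(masks_t0)
        registration_report = []
        if config.mode == "predict_t12":
            stage = "register"
            reg_dir = out / "registered_masks"
            reg_dir.mkdir(exist_ok=True)
            for _, row in table.iterrows():
                sid = row["sample_id"]
                if pd.isna(row.get("image_t12_moved")) or pd.isna(row.get("mask_t12_moved")):
                    raise RuntimeError(f"stage register: sample {sid} lacks follow-up files")
                moving = fio.read_image(row["image_t12_moved"])
                moving_mask = fio.read_mask(row["mask_t12_moved"])
                # register at native resolution against the unresized baseline
                fixed = (images[sid] if moving.shape == images[sid].shape
                         else fio.read_image(row["image"]))
                tf, warped = register_pair(fixed, moving, moving_mask, seed=config.seed)
                rec = {"sample_id": sid, **tf.to_json(),
                       "residual_rms": tf.residual_rms}
                if "mask_t12_true" in row and not pd.isna(row["mask_t12_true"]):
                    gt = fio.read_mask(row["mask_t12_true"])
                    if gt.shape == warped.shape:
                        rec["dice_vs_true_t12"] = evaluate_pair(warped, gt).dice
                registration_report.append(rec)
                if warped.shape != (config.input_size,) * 2:
                    warped = standardize(np.full(warped.shape, 0.5), warped,
                                         target_size=config.input_size)[1]
                labels[sid] = warped
                fio.write_mask(reg_dir / f"{sid}.png", warped)
            pd.DataFrame(registration_report).to_csv(out / "registration.csv", index=False)

        stage = "fold_plan"
        plan = make_fold_plan(table, config.n_folds, config.n_validation, seed=config.seed)
        plan.verify(table)
        plan.save(out / "fold_plan.json")

        model_specs = {"attn_unet": True}
        if config.mode == "segment_t0":
            model_specs["unet"] = False

        per_image: dict[str, list] = {name: [] for name in model_specs}
        mask_dir = out / "pred_masks"
        mask_dir.mkdir(exist_ok=True)
        for k in range(plan.n_folds):
            train_ids, val_ids, test_ids = plan.fold(k)
            X = np.stack([images[s] for s in train_ids])
            y = np.stack([labels[s] for s in train_ids])
            val = (
                (np.stack([images[s] for s in val_ids]),
                 np.stack([labels[s] for s in val_ids]))
                if val_ids else None
            )
            X_test = np.stack([images[s] for s in test_ids])
            for name, attended in model_specs.items():
                stage = f"train fold {k} ({name})"
                est = AttentionUNetSegmenter(
                    depth=config.depth, base_filters=config.base_filters,
                    temperature=config.temperature, attended=attended,
                    loss=config.loss, learning_rate=config.learning_rate,
                    batch_size=config.batch_size, epochs=config.epochs,
                    random_state=config.seed,
                )
                est.fit(X, y, validation_data=val)
                est.history_.to_csv(out / f"history_{name}_fold{k}.csv", index=False)
                stage = f"predict fold {k} ({name})"
                preds = est.predict(X_test)
                for sid, pred in zip(test_ids, preds):
                    fio.write_mask(mask_dir / f"{name}_{sid}.png", pred)
                    ms = evaluate_pair(pred, labels[sid])
                    per_image[name].append(
                        {"sample_id": sid, "fold": k, **ms.as_dict()}
                    )
                if config.heatmaps and test_ids:
                    stage = f"visualize fold {k} ({name})"
                    img0 = images[test_ids[0]]
                    if attended:
                        hm = attention_heatmap(est.model_, img0, config.depth - 1)
                    else:
                        hm = deconv_reconstruct(est.model_, img0, config.depth - 1)
                    save_heatmap_png(hm, out / f"heatmap_{name}_fold{k}.png", overlay=img0)

        stage = "evaluate"
        tables = {}
        for name, rows in per_image.items():
            df = pd.DataFrame(rows)
            df.to_csv(out / f"per_image_{name}.csv", index=False)
            summarize_metrics(df).to_csv(out / f"summary_{name}.csv", index=False)
            tables[name] = df
        if len(tables) == 2:
            comparison_table(
                tables["unet"], tables["attn_unet"], "unet", "attn_unet"
            ).to_csv(out / "comparison.csv", index=False)

        manifest = {
            "mode": config.mode,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "n_samples": int(len(table)),
            "folds": plan.to_json(),
            "input_hash": _content_hash(table),
            "versions": _versions(),
        }
        fio.write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:  # surface the failing stage, per the run contract
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc


def _versions() -> dict:
    import scipy
    import skimage
    import sklearn

    from . import __version__

    return {
        "fafseg": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
    }
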