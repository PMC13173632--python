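"""End-to-end orchestration: phantom generation -> training ->
segmentation -> length measurement -> screening evaluation, driven by
a single validated configuration with one global seed.

Every run writes a resolved copy of its configuration and a
``run.log``; a failed stage leaves partial outputs behind alongside a
``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .caliper import measure_all
from .objectives import LossConfig, dice_coefficient, ssim
from .phantoms import generate_cohort, generate_phantom, random_phantom_spec
from .resunet import ModelConfig, build_model, load_model, predict_mask, save_model
from .screening import evaluate_cohort
from .trainer import SplitConfig, TrainConfig, split_dataset, train

log = logging.getLogger("cervitrace")

_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "log_level": str,
    "stages": list,
    "phantom": {
        "count": int, "image_shape_px": list, "pixel_spacing_mm": float,
        "write_files": bool,
    },
    "train": {
        "base_channels": int, "batch_size": int, "max_epochs": int,
        "learning_rate": float, "patience": int, "monitor": str,
    },
    "segment": {"checkpoint": str},
    "measure": {"smooth_window": object},
    "evaluate": {"n_term": int, "n_32_36": int, "n_lt32": int, "use_mom": bool,
                 "cohort_csv": str},
}

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "cervitrace_run",
    "log_level": "INFO",
    "stages": ["phantom", "train", "segment", "measure", "evaluate"],
    "phantom": {"count": 50, "image_shape_px": [64, 128],
                "pixel_spacing_mm": 0.35, "write_files": False},
    "train": {"base_channels": 8, "batch_size": 16, "max_epochs": 20,
              "learning_rate": 1e-3, "patience": 10, "monitor": "train_loss"},
    "segment": {},
    "measure": {"smooth_window": "auto"},
    "evaluate": {"n_term": 400, "n_32_36": 30, "n_lt32": 6, "use_mom": False},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge over defaults, rejecting unknown keys at either level."""
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(_SCHEMA[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub in value:
                if sub not in _SCHEMA[key]:
                    raise ConfigError(f"unknown key {key}.{sub}")
            merged[key].update(value)
        else:
            merged[key] = value
    unknown_stages = set(merged["stages"]) - {"phantom", "train", "segment",
                                              "measure", "evaluate"}
    if unknown_stages:
        raise ConfigError(f"unknown stages {sorted(unknown_stages)}")
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def run_pipeline(config: dict | str | Path) -> int:
    """Execute the requested stages; returns 0 on success, 1 on any
    stage failure (partial outputs retained with a FAILED marker)."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config["log_level"])
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config))
    seed = int(config["seed"])
    log.info("pipeline start; seed=%d stages=%s", seed, config["stages"])

    state: dict = {}
    try:
        for stage in ["phantom", "train", "segment", "measure", "evaluate"]:
            if stage in config["stages"]:
                log.info("stage %s", stage)
                globals()[f"_stage_{stage}"](config, seed, out, state)
    except Exception as exc:  # pragma: no cover - exercised via CLI tests
        (out / "FAILED").write_text(f"stage failure: {exc}\n")
        log.exception("pipeline failed")
        return 1
    finally:
        log.removeHandler(handler)
        handler.close()
    return 0


def _stage_phantom(config, seed, out, state):
    pc = config["phantom"]
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(pc["count"]):
        spec = random_phantom_spec(
            rng, image_shape_px=tuple(pc["image_shape_px"]),
            pixel_spacing_mm=pc["pixel_spacing_mm"],
        )
        img, mask, truth = generate_phantom(spec)
        img.image_id = mask.image_id = f"phantom{i:04d}"
        phantoms.append((img, mask, truth))
    state["phantoms"] = phantoms
    if pc.get("write_files"):
        pdir = out / "phantoms"
        pdir.mkdir(exist_ok=True)
        for img, mask, truth in phantoms:
            ctio.write_image(img, pdir / f"{img.image_id}.tif")
            ctio.write_mask(mask, pdir / f"{img.image_id}_mask.png")
            ctio.write_ground_truth(truth, pdir / f"{img.image_id}_truth.json")
    manifest = [p[0].image_id for p in phantoms]
    (out / "phantom_manifest.json").write_text(json.dumps(manifest))


def _stage_train(config, seed, out, state):
    tc = config["train"]
    phantoms = state["phantoms"]
    shape = phantoms[0][0].shape
    pairs = [(img, mask) for img, mask, _ in phantoms]
    tr, va, te = split_dataset(pairs, SplitConfig(seed=seed))
    state["splits"] = (tr, va, te)
    (out / "split_manifest.json").write_text(json.dumps({
        "train": [p[0].image_id for p in tr],
        "val": [p[0].image_id for p in va],
        "test": [p[0].image_id for p in te],
    }, indent=2))
    model = build_model(ModelConfig(input_shape=shape,
                                    base_channels=tc["base_channels"],
                                    seed=seed))
    model, hist = train(
        model, tr, va, LossConfig(),
        TrainConfig(batch_size=tc["batch_size"], max_epochs=tc["max_epochs"],
                    learning_rate=tc["learning_rate"],
                    early_stopping_patience=tc["patience"],
                    monitor=tc["monitor"], seed=seed),
    )
    pd.DataFrame({
        "epoch": hist.epochs, "train_loss": hist.train_loss,
        "val_loss": hist.val_loss, "train_acc": hist.train_acc,
        "val_acc": hist.val_acc,
    }).to_csv(out / "history.csv", index=False)
    save_model(model, out / "checkpoint")
    state["model"] = model


def _stage_segment(config, seed, out, state):
    sc = config["segment"]
    model = state.get("model")
    if model is None:
        ckpt = sc.get("checkpoint")
        if ckpt is None:
            raise ConfigError("segment stage needs a trained model or checkpoint")
        model = load_model(ckpt)
    targets = state.get("splits", (None, None, None))[2]
    if targets is None:
        targets = [(img, mask) for img, mask, _ in state["phantoms"]]
    rows, masks = [], []
    for img, truth_mask in targets:
        prob, mask = predict_mask(model, img)
        masks.append((img.image_id, mask))
        rows.append({
            "image_id": img.image_id,
            "dice": dice_coefficient(truth_mask, mask),
            "ssim": ssim(truth_mask.pixels.astype(float),
                         mask.pixels.astype(float)),
        })
    state["predicted_masks"] = masks
    pd.DataFrame(rows).to_csv(out / "segmentation_metrics.csv", index=False)


def _stage_measure(config, seed, out, state):
    mc = config["measure"]
    masks = state.get("predicted_masks")
    if masks is None:
        masks = [(m.image_id, m) for _, m, _ in state["phantoms"]]
    rows = []
    for image_id, mask in masks:
        try:
            m = measure_all(mask, smooth_window=mc["smooth_window"])
            rows.append({
                "image_id": image_id,
                "single_line_mm": m.single_line_mm,
                "two_line_mm": m.two_line_mm,
                "ai_line_mm": m.ai_line_mm,
                "trace_point_count": m.trace_point_count,
                "flags": m.n_components_merged,
            })
        except ValueError as exc:
            rows.append({"image_id": image_id, "error": str(exc)})
    pd.DataFrame(rows).to_csv(out / "measurements.csv", index=False)


def _stage_evaluate(config, seed, out, state):
    ec = config["evaluate"]
    if ec.get("cohort_csv"):
        cohort = ctio.read_cohort(ec["cohort_csv"])
    else:
        cohort = generate_cohort(ec["n_term"], ec["n_32_36"], ec["n_lt32"],
                                 seed=seed)
    ctio.write_cohort(cohort, out / "cohort.csv")
    report = evaluate_cohort(cohort, use_mom=ec["use_mom"])
    report["summary"].to_csv(out / "summary.csv", index=False)
    roc_rows = []
    for m, r in report["roc"].items():
        if r is not None:
            roc_rows.append({"method": m, "auroc": r.auroc, "ci_low": r.ci_low,
                             "ci_high": r.ci_high, "n_cases": r.n_cases,
                             "n_controls": r.n_controls})
    pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
    cmp_rows = [{"comparison": k, "delta_auroc": v.delta_auroc,
                 "p_value": v.p_value}
                for k, v in report["roc_comparisons"].items()]
    pd.DataFrame(cmp_rows).to_csv(out / "roc_comparisons.csv", index=False)
    mom = pd.concat(report["mom"].values(), ignore_index=True)
    mom.to_csv(out / "mom.csv", index=False)
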