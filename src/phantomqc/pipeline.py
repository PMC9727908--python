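"""End-to-end orchestration: synth -> preprocess -> dataset -> train ->
score -> evaluate, with a JSON run manifest.

The pipeline keeps its artifacts in memory (optionally mirrored to disk)
and records per-stage counts, seeds and content hashes so that re-running
any stage with unchanged inputs reproduces its manifest entries exactly.
Desk-scale defaults (two devices, a handful of images, a reduced-input
network) keep a full run in the minutes range on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cnn_model, dataset, evaluation, scoring
from .classes import class_index
from .errors import DependencyError, InvalidArgumentError
from .phantom_synth import generate_phantom, make_device_profiles
from .preprocess import PreprocessConfig, preprocess_image

STAGES = ("synth", "preprocess", "dataset", "train", "score", "evaluate")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with desk-scale defaults."""

    n_devices: int = 2
    images_per_device: int = 6
    dose_factor: float = 4.0
    architecture: str = "CNN1"
    input_size: int = 32
    epochs: int = 3
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    split_ratio: float = 0.9
    balance: bool = False
    score_mode: str = "strict"
    pass_thresholds: tuple = scoring.DEFAULT_PASS_THRESHOLDS
    seed: int = 0
    out_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


def validate_config(config: RunConfig) -> list[str]:
    """Errors/warnings as strings; an empty list means a clean config."""
    findings = []
    try:
        squares = config.preprocess.target_squares
        if len(squares) != 16:
            findings.append(f"error: expected 16 target squares, found {len(squares)}")
    except Exception as exc:  # degenerate config object
        findings.append(f"error: preprocess config invalid: {exc}")
    if config.n_devices < 1:
        findings.append("error: n_devices must be >= 1")
    if config.images_per_device < 2:
        findings.append("error: images_per_device must be >= 2 for a split")
    if not config.dose_factor > 0:
        findings.append("error: dose_factor must be > 0")
    if config.architecture not in cnn_model.ARCHITECTURE_TABLE:
        findings.append(f"error: unknown architecture {config.architecture}")
    n_subs = 16 * config.n_devices * config.images_per_device
    if config.batch_size > n_subs:
        findings.append(
            f"error: batch size {config.batch_size} exceeds corpus size {n_subs}")
    if config.epochs < 1:
        findings.append("error: epochs must be >= 1")
    if not 0 < config.split_ratio < 1:
        findings.append("error: split ratio must be in (0, 1)")
    return findings


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: tuple | list | None = None,
                 ) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    The manifest maps stage name -> {counts, hashes, elapsed}; requesting a
    stage whose prerequisite was not run raises ``DependencyError`` naming
    the missing stage.
    """
    findings = [f for f in validate_config(config) if f.startswith("error")]
    if findings:
        raise InvalidArgumentError("; ".join(findings))
    requested = list(STAGES) if stages is None else [s for s in STAGES
                                                    if s in set(stages)]
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise InvalidArgumentError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {"config": {k: v for k, v in dataclasses.asdict(config).items()
                                 if k != "preprocess"},
                      "stages": {}}
    state: dict = {}

    def _require(stage: str, key: str) -> None:
        if key not in state:
            raise DependencyError(f"stage '{stage}' requires '{key}' output")

    for stage in requested:
        t0 = time.monotonic()
        entry: dict = {}
        if stage == "synth":
            profiles = make_device_profiles(config.n_devices, config.seed)
            images = []
            for d, prof in enumerate(profiles):
                for i in range(config.images_per_device):
                    img, gt = generate_phantom(
                        prof, config.dose_factor,
                        seed=config.seed + 1000 * d + i)
                    images.append((f"{prof.device_id}_img{i:03d}", img, gt))
            state["images"] = images
            entry["counts"] = {"devices": len(profiles), "images": len(images)}
            entry["hash"] = _hash(images[0][1].pixels)
        elif stage == "preprocess":
            _require(stage, "images")
            per_image = []
            for k, (img_id, img, gt) in enumerate(state["images"]):
                subs = preprocess_image(img, config.preprocess,
                                        seed=config.seed + k, source_id=img_id,
                                        size=config.input_size)
                per_image.append((img_id, subs, gt))
            state["subimages"] = per_image
            entry["counts"] = {"images": len(per_image),
                               "subimages": sum(len(s) for _, s, _ in per_image)}
        elif stage == "dataset":
            _require(stage, "subimages")
            train_imgs, val_imgs = dataset.split_images(
                state["subimages"], config.split_ratio, config.seed)
            def _labeled(items, split):
                out = []
                for img_id, subs, gt in items:
                    out.extend(dataset.label_subimages(subs, gt.points, split))
                return out
            train_subs = _labeled(train_imgs, "train")
            val_subs = _labeled(val_imgs, "val")
            if config.balance:
                train_subs, _m = dataset.balance_and_augment(
                    train_subs, seed=config.seed,
                    n_train_images=len(train_imgs))
            state["corpus"] = (train_subs, val_subs)
            state["val_images"] = val_imgs
            entry["counts"] = {"train_images": len(train_imgs),
                               "val_images": len(val_imgs),
                               "train_subimages": len(train_subs),
                               "val_subimages": len(val_subs)}
        elif stage == "train":
            _require(stage, "corpus")
            train_subs, val_subs = state["corpus"]
            spec = cnn_model.spec_for(config.architecture, config.input_size)
            model = cnn_model.build(spec, seed=config.seed)
            def _arrays(subs):
                x = np.stack([ls.sub.pixels for ls in subs])[:, None]
                y = np.array([class_index(ls.label) for ls in subs])
                return x, y
            tc = cnn_model.TrainConfig(learning_rate=config.learning_rate,
                                       momentum=config.momentum,
                                       batch_size=config.batch_size,
                                       epochs=config.epochs, seed=config.seed)
            model, history = cnn_model.train(model, _arrays(train_subs),
                                             _arrays(val_subs or train_subs), tc)
            state["model"] = model
            state["history"] = history
            entry["counts"] = {"epochs": len(history),
                               "parameters": model.n_parameters()}
            entry["best_val_accuracy"] = max(h["val_accuracy"] for h in history)
        elif stage == "score":
            _require(stage, "model")
            _require(stage, "subimages")
            model_sheets, truth_sheets = {}, {}
            for img_id, subs, gt in state["subimages"]:
                preds = {}
                for sub in subs:
                    _, pred = cnn_model.predict(model=state["model"], sub=sub,
                                                mode=config.score_mode)
                    preds[sub.position] = pred
                model_sheets[img_id] = scoring.predictions_to_sheet(
                    preds, mode=config.score_mode, image_id=img_id)
                truth_sheets[img_id] = scoring.ScoreSheet.from_points(
                    gt.points, source="ground-truth", image_id=img_id)
            state["model_sheets"] = model_sheets
            state["truth_sheets"] = truth_sheets
            n_pass = sum(scoring.sheet_passes(s, config.pass_thresholds)
                         for s in model_sheets.values())
            entry["counts"] = {"sheets": len(model_sheets), "passing": n_pass}
        elif stage == "evaluate":
            _require(stage, "model_sheets")
            report = evaluation.score_agreement_report(
                state["truth_sheets"], state["model_sheets"])
            state["report"] = report
            entry["counts"] = {"families": len(report)}
            entry["fraction_equal"] = {k: v["fraction_equal"]
                                       for k, v in report.items()}
        entry["elapsed_s"] = round(time.monotonic() - t0, 3)
        manifest["stages"][stage] = entry

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_state"] = state  # in-memory artifacts for callers
    return manifest
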