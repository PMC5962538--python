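"""End-to-end pipeline: synth -> train -> predict -> calibrate/locate -> evaluate.

Every stage reads and writes files under a single output directory, recorded
in a JSON run manifest, so any stage can be rerun from the manifest alone.
Seeds are mandatory; given the same manifest the deterministic stages are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import evaluation, io, localisation, synthetic
from .localisation import RecoveryParams
from .network import forward, init_params, load_checkpoint, save_checkpoint
from .training import TrainingConfig, preprocess, train

__all__ = ["STAGES", "run_pipeline", "synth_stage", "train_stage",
           "predict_stage", "calibrate_stage", "locate_stage",
           "evaluate_stage"]

STAGES = ("synth", "train", "predict", "calibrate", "locate", "evaluate")


def _require(path: Path, stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{stage}' stage first")
    return path


def synth_stage(out: Path, n_images: int, healthy_fraction: float, seed: int,
                height: int = 128, width: int = 128,
                val_fraction: float = 0.15,
                test_fraction: float = 0.25) -> dict:
    """Generate a synthetic dataset and write images, truth and a manifest.

    The split is stratified by regime: within each regime the last images go
    to test, the ones before to validation, the rest to training.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    samples = synthetic.generate_dataset(n_images, healthy_fraction, seed,
                                         height=height, width=width)
    records = []
    for i, s in enumerate(samples):
        stem = f"{s.regime}_{i:03d}"
        io.save_image(out / f"{stem}.tif", s.image)
        io.save_centroids(out / f"{stem}.csv", s.centroids)
        io.save_mask(out / f"{stem}_mask.png", s.mask)
        records.append({
            "image": f"{stem}.tif", "centroids": f"{stem}.csv",
            "mask": f"{stem}_mask.png", "regime": s.regime,
            "disk_radius": s.disk_radius,
            "spec": dataclasses.asdict(s.spec),
        })
    for regime in ("healthy", "disease"):
        idx = [i for i, r in enumerate(records) if r["regime"] == regime]
        n_test = max(1, int(round(test_fraction * len(idx)))) if idx else 0
        n_val = max(1, int(round(val_fraction * len(idx)))) if idx else 0
        for j, i in enumerate(idx):
            if j >= len(idx) - n_test:
                records[i]["split"] = "test"
            elif j >= len(idx) - n_test - n_val:
                records[i]["split"] = "val"
            else:
                records[i]["split"] = "train"
    manifest = {"seed": seed, "n_images": n_images,
                "healthy_fraction": healthy_fraction,
                "height": height, "width": width, "images": records}
    io.save_manifest(out / "manifest.json", manifest)
    return manifest


def _load_split(out: Path, manifest: dict, split: str):
    pairs, names, regimes, truths = [], [], [], []
    for rec in manifest["images"]:
        if rec["split"] != split:
            continue
        img = io.load_image(out / rec["image"])
        mask = io.load_mask(out / rec["mask"])
        pairs.append((img, mask))
        names.append(rec["image"])
        regimes.append(rec["regime"])
        truths.append(io.load_centroids(out / rec["centroids"]))
    return pairs, names, regimes, truths


def train_stage(out: Path, config: TrainingConfig, units: int = 32,
                hidden: int = 64) -> Path:
    out = Path(out)
    manifest = io.load_manifest(_require(out / "manifest.json", "synth"))
    train_pairs, *_ = _load_split(out, manifest, "train")
    val_pairs, *_ = _load_split(out, manifest, "val")
    params0 = init_params(config.seed, units=units, hidden=hidden)
    params, history = train(train_pairs, val_pairs, config, params=params0)
    ckpt = out / "checkpoint.npz"
    save_checkpoint(ckpt, params, config={
        "training": dataclasses.asdict(config),
        "best_epoch": history.best_epoch,
        "stopped_epoch": history.stopped_epoch})
    hist = np.column_stack([history.train_loss, history.val_loss,
                            history.val_dice])
    header = "train_loss,val_loss,val_dice"
    np.savetxt(out / "history.csv", hist, delimiter=",", header=header,
               comments="")
    return ckpt


def predict_stage(out: Path, splits=("val", "test")) -> list[Path]:
    out = Path(out)
    manifest = io.load_manifest(_require(out / "manifest.json", "synth"))
    params = load_checkpoint(_require(out / "checkpoint.npz", "train"))
    written = []
    for rec in manifest["images"]:
        if rec["split"] not in splits:
            continue
        img = io.load_image(out / rec["image"])
        probs = forward(preprocess(img), params)
        path = out / (Path(rec["image"]).stem + "_prob.tif")
        io.save_image(path, probs[..., 1])
        written.append(path)
    return written


def _params_dict(p: RecoveryParams) -> dict:
    return dataclasses.asdict(p)


def calibrate_stage(out: Path) -> dict:
    """Calibrate (sigma, T) on the validation set for healthy/disease/both."""
    out = Path(out)
    manifest = io.load_manifest(_require(out / "manifest.json", "synth"))
    _, names, regimes, truths = _load_split(out, manifest, "val")
    maps = [np.asarray(io.load_image(out / (Path(n).stem + "_prob.tif")))
            for n in names]
    for n in names:
        _require(out / (Path(n).stem + "_prob.tif"), "predict")
    subsets = {
        "both": list(range(len(names))),
        "healthy": [i for i, r in enumerate(regimes) if r == "healthy"],
        "disease": [i for i, r in enumerate(regimes) if r == "disease"],
    }
    result = {}
    for key, idx in subsets.items():
        if not idx:
            continue
        p = localisation.calibrate([maps[i] for i in idx],
                                   [truths[i] for i in idx])
        result[key] = _params_dict(p)
    io.save_manifest(out / "recovery_params.json", result)
    return result


def _load_recovery(out: Path) -> dict[str, RecoveryParams]:
    raw = io.load_manifest(_require(out / "recovery_params.json", "calibrate"))
    return {k: RecoveryParams(**v) for k, v in raw.items()}


def locate_stage(out: Path, split: str = "test") -> list[Path]:
    out = Path(out)
    manifest = io.load_manifest(_require(out / "manifest.json", "synth"))
    params = _load_recovery(out)
    pb = params["both"]
    ph = params.get("healthy", pb)
    ps = params.get("disease", pb)
    written = []
    for rec in manifest["images"]:
        if rec["split"] != split:
            continue
        prob = io.load_image(
            _require(out / (Path(rec["image"]).stem + "_prob.tif"), "predict"))
        est = localisation.adaptive_localise(np.asarray(prob), pb, ph, ps)
        path = out / (Path(rec["image"]).stem + "_est.csv")
        io.save_centroids(path, est)
        written.append(path)
    return written


def evaluate_stage(out: Path, split: str = "test") -> dict:
    out = Path(out)
    manifest = io.load_manifest(_require(out / "manifest.json", "synth"))
    per_image = []
    counts = []
    for rec in manifest["images"]:
        if rec["split"] != split:
            continue
        stem = Path(rec["image"]).stem
        truth = io.load_centroids(out / rec["centroids"])
        est = io.load_centroids(_require(out / f"{stem}_est.csv", "locate"))
        res = evaluation.match(est, truth)
        entry = {"image": rec["image"], "regime": rec["regime"],
                 "tp": res.tp, "fp": res.fp, "fn": res.fn,
                 "tolerance": res.tolerance,
                 "n_true": int(res.tp + res.fn),
                 "n_est": int(res.tp + res.fp)}
        if res.tp + res.fp + res.fn == 0:
            entry["dice"] = None
            entry["flag"] = "empty truth and empty estimate"
        else:
            entry["dice"] = evaluation.dice(res)
            if res.tp + res.fn == 0:
                entry["flag"] = "no true cones; Dice forced by false positives"
        per_image.append(entry)
        counts.append((entry["n_est"], entry["n_true"]))
    report = {"split": split, "per_image": per_image}
    scores = [e["dice"] for e in per_image if e["dice"] is not None]
    regs = [e["regime"] for e in per_image if e["dice"] is not None]
    for regime in ("healthy", "disease"):
        vals = [s for s, r in zip(scores, regs) if r == regime]
        if vals:
            report[f"dice_{regime}_mean"] = float(np.mean(vals))
            report[f"dice_{regime}_sd"] = float(np.std(vals, ddof=1)) \
                if len(vals) > 1 else 0.0
    if scores:
        report["dice_mean"] = float(np.mean(scores))
    if len(counts) >= 3:
        ba = evaluation.bland_altman(counts)
        report["bland_altman"] = dataclasses.asdict(ba)
    io.save_manifest(out / "report.json", report)
    return report


def run_pipeline(out, stages=STAGES, n_images: int = 20,
                 healthy_fraction: float = 0.5, seed: int = 0,
                 height: int = 128, width: int = 128, units: int = 8,
                 config: TrainingConfig | None = None) -> dict:
    """Run the requested stages in order and return the final report (if any)."""
    out = Path(out)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    report = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "synth":
            synth_stage(out, n_images, healthy_fraction, seed,
                        height=height, width=width)
        elif stage == "train":
            cfg = config or TrainingConfig(seed=seed)
            train_stage(out, cfg, units=units)
        elif stage == "predict":
            predict_stage(out)
        elif stage == "calibrate":
            calibrate_stage(out)
        elif stage == "locate":
            locate_stage(out)
        elif stage == "evaluate":
            report = evaluate_stage(out)
    return report
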