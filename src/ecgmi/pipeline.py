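"""Pipeline orchestration: synth -> preprocess -> features -> augment ->
train -> evaluate, driven by one YAML config.

Every stage reads and writes plain-text artifacts (CSV/JSON) in the output
directory, so stages can be re-run standalone and a fused run is bitwise
reproducible.  Each stage derives its RNG seed from the global seed and
the stage name (CRC-32 substream hashing), so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augmentation import AugmentConfig, LabeledFeatureSet, augment, permute_blocks, window_slice
from .estimators import SSSDRNClassifier
from .io import read_features, read_manifest, read_record, write_features, write_manifest, write_record
from .metrics import MetricsReport, split
from .network import load_params, save_params
from .preprocessing import MedianFilterConfig, denoise_record
from .records import ECGRecord, MIParams, NoiseSpec, SynthConfig
from .staticfeat import AssembleConfig, assemble
from .synth import add_noise, generate_record

log = logging.getLogger("ecgmi")

STAGES = ("synth", "preprocess", "features", "augment", "train", "evaluate")


class PipelineConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream: stable per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise PipelineConfigError("pipeline config must be a mapping")
    if "seed" not in config:
        raise PipelineConfigError("pipeline config lacks the 'seed' field")
    for stage in STAGES:
        if stage not in config:
            raise PipelineConfigError(f"pipeline config lacks the {stage!r} stage block")
        if not isinstance(config[stage], dict):
            raise PipelineConfigError(f"stage block {stage!r} must be a mapping")


def default_config(seed: int = 0) -> dict:
    """A small, fully synthetic end-to-end configuration."""
    return {
        "seed": seed,
        "synth": {
            "n_per_class": 12,
            "duration_s": 10.0,
            "heart_rate_bpm": 70.0,
            "fs": 500.0,
            "n_leads": 2,
            "rr_jitter": 0.03,
            "amp_jitter": 0.05,
            "noise": [
                {"kind": "baseline_wander", "amplitude": 0.1, "frequency": 0.3},
                {"kind": "powerline", "amplitude": 0.03, "frequency": 50.0},
                {"kind": "impulse", "amplitude": 0.5, "impulse_rate": 1.0},
                {"kind": "gaussian", "amplitude": 0.02},
            ],
        },
        "preprocess": {"window_len": 5},
        "features": {"n_signal_augments": 1},
        "augment": {"multiplier": 3.0, "D": 4, "ws_fraction": 0.9,
                    "random_gen_fraction": 0.3, "jitter": 0.01},
        "train": {"preset": "tiny", "pop_size": 24, "n_iter": 120, "lb": -0.7,
                  "ub": 0.7, "learning_pct": 0.7},
        "evaluate": {},
    }


# ---------------------------------------------------------------------------
# stages

def run_synth(config: dict, outdir: Path) -> Path:
    c = config["synth"]
    seed = stage_seed(config["seed"], "synth")
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    idx = 0
    for mi in (False, True):
        for j in range(int(c.get("n_per_class", 8))):
            rec_seed = (seed + 7919 * idx) % (2 ** 31)
            sc = SynthConfig(
                duration_s=float(c.get("duration_s", 10.0)),
                heart_rate_bpm=float(c.get("heart_rate_bpm", 70.0)),
                fs=float(c.get("fs", 500.0)),
                mi=mi,
                rr_jitter=float(c.get("rr_jitter", 0.0)),
                amp_jitter=float(c.get("amp_jitter", 0.0)),
                n_leads=int(c.get("n_leads", 1)),
                seed=rec_seed,
            )
            record = generate_record(sc)
            for k, ns in enumerate(c.get("noise", [])):
                spec = NoiseSpec(seed=(rec_seed + 31 * k + 1) % (2 ** 31),
                                 **{key: v for key, v in ns.items() if key != "seed"})
                record = add_noise(record, spec)
            rec_id = f"rec{idx:04d}"
            path = outdir / f"{rec_id}.csv"
            write_record(record, path)
            entries.append({"id": rec_id, "path": path.name, "label": record.label})
            idx += 1
    manifest = outdir / "manifest.csv"
    write_manifest(entries, manifest)
    log.info("synth: wrote %d records to %s", idx, outdir)
    return manifest


def run_preprocess(config: dict, indir: Path, outdir: Path) -> Path:
    c = config["preprocess"]
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(indir / "manifest.csv")
    mf = MedianFilterConfig(window_len=int(c.get("window_len", 5)))
    entries = []
    for _, row in manifest.iterrows():
        record = read_record(indir / row["path"], format="csv", label=row["label"])
        filtered = denoise_record(record, mf)
        path = outdir / row["path"]
        write_record(filtered, path)
        entries.append({"id": row["id"], "path": path.name, "label": row["label"]})
    out_manifest = outdir / "manifest.csv"
    write_manifest(entries, out_manifest)
    log.info("preprocess: filtered %d records", len(entries))
    return out_manifest


def run_features(config: dict, indir: Path, out_csv: Path) -> Path:
    """Feature extraction; optionally adds signal-level augmented copies
    (segment permutation + window slicing) before extraction."""
    c = config["features"]
    seed = stage_seed(config["seed"], "features")
    rng = np.random.default_rng(seed)
    manifest = read_manifest(indir / "manifest.csv")
    ac = AssembleConfig()
    rows, labels, flags = [], [], []
    n_aug = int(c.get("n_signal_augments", 0))
    aug_cfg = config.get("augment", {})
    for _, row in manifest.iterrows():
        record = read_record(indir / row["path"], format="csv", label=row["label"])
        rows.append(assemble(record, ac).values)
        labels.append(record.label)
        flags.append(False)
        for _ in range(n_aug):
            perturbed = np.vstack([
                window_slice(permute_blocks(lead, int(aug_cfg.get("D", 4)), rng),
                             float(aug_cfg.get("ws_fraction", 0.9)), rng)
                for lead in record.samples
            ])
            aug_rec = ECGRecord(samples=perturbed, fs=record.fs,
                                lead_names=record.lead_names, label=record.label)
            rows.append(assemble(aug_rec, ac).values)
            labels.append(record.label)
            flags.append(True)
    fset = LabeledFeatureSet(np.vstack(rows), np.array(labels), np.array(flags), ac.layout())
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    write_features(fset, out_csv)
    log.info("features: %d rows (%d signal-augmented)", fset.n_rows, sum(flags))
    return out_csv


def run_augment(config: dict, in_csv: Path, out_csv: Path) -> Path:
    c = config["augment"]
    fset = read_features(in_csv)
    cfg = AugmentConfig(
        multiplier=float(c.get("multiplier", 3.0)),
        D=int(c.get("D", 4)),
        ws_fraction=float(c.get("ws_fraction", 0.9)),
        random_gen_fraction=float(c.get("random_gen_fraction", 0.3)),
        jitter=float(c.get("jitter", 0.01)),
        seed=stage_seed(config["seed"], "augment"),
    )
    out = augment(fset, cfg)
    write_features(out, out_csv)
    log.info("augment: %d -> %d rows, counts %s", fset.n_rows, out.n_rows, out.class_counts())
    return out_csv


def run_train(config: dict, features_csv: Path, outdir: Path,
              augmented_csv: Path | None = None) -> dict:
    """Split the feature table, augment the training split only, fit.

    Holding out rows before augmentation keeps synthetic rows (envelope
    random generation, interpolation resampling) out of the evaluation
    set, so the reported metrics are computed on untouched records.
    """
    c = config["train"]
    outdir.mkdir(parents=True, exist_ok=True)
    fset = read_features(features_csv)
    seed = stage_seed(config["seed"], "train")
    p = float(c.get("learning_pct", 0.7))
    (train_idx, test_idx), = split(fset.labels, "learning_pct", p, seed=seed)
    train_set = LabeledFeatureSet(fset.matrix[train_idx], fset.labels[train_idx],
                                  fset.augmented[train_idx], fset.layout)
    a = config["augment"]
    aug = augment(train_set, AugmentConfig(
        multiplier=float(a.get("multiplier", 3.0)),
        D=int(a.get("D", 4)),
        ws_fraction=float(a.get("ws_fraction", 0.9)),
        random_gen_fraction=float(a.get("random_gen_fraction", 0.3)),
        jitter=float(a.get("jitter", 0.01)),
        seed=stage_seed(config["seed"], "augment"),
    ))
    if augmented_csv is not None:
        write_features(aug, augmented_csv)
    clf = SSSDRNClassifier(
        preset=c.get("preset", "tiny"),
        pop_size=int(c.get("pop_size", 20)),
        n_iter=int(c.get("n_iter", 60)),
        lb=float(c.get("lb", -0.7)), ub=float(c.get("ub", 0.7)),
        random_state=seed,
    )
    clf.fit(aug.matrix, aug.labels)
    save_params(clf.spec_, clf.params_, outdir / "network_spec.json", outdir / "weights.csv")
    np.savetxt(outdir / "convergence.csv", np.asarray(clf.convergence_), delimiter=",")
    scaler = {"mean": clf.mean_.tolist(), "scale": clf.scale_.tolist(),
              "classes": clf.classes_.tolist(), "standardize": clf.standardize}
    (outdir / "scaler.json").write_text(json.dumps(scaler))
    split_info = {"train": train_idx.tolist(), "test": test_idx.tolist(), "learning_pct": p}
    (outdir / "split.json").write_text(json.dumps(split_info))
    log.info("train: fitness %.4f after %d iterations", clf.best_fitness_, len(clf.convergence_))
    return {"classifier": clf, "train_idx": train_idx, "test_idx": test_idx}


def _load_classifier(train_dir: Path) -> SSSDRNClassifier:
    spec, params = load_params(train_dir / "network_spec.json", train_dir / "weights.csv")
    scaler = json.loads((train_dir / "scaler.json").read_text())
    clf = SSSDRNClassifier(preset=spec.preset if spec.preset != "custom" else "tiny")
    clf.spec_ = spec
    clf.params_ = params
    clf.classes_ = np.array(scaler["classes"])
    clf.mean_ = np.array(scaler["mean"])
    clf.scale_ = np.array(scaler["scale"])
    clf.standardize = scaler["standardize"]
    trace_path = train_dir / "convergence.csv"
    if trace_path.exists():
        clf.convergence_ = np.atleast_1d(np.loadtxt(trace_path, delimiter=",")).tolist()
    return clf


def run_evaluate(config: dict, features_csv: Path, train_dir: Path, out_json: Path) -> MetricsReport:
    fset = read_features(features_csv)
    clf = _load_classifier(train_dir)
    split_info = json.loads((train_dir / "split.json").read_text())
    test_idx = np.asarray(split_info["test"], dtype=int)
    X, y = fset.matrix[test_idx], fset.labels[test_idx]
    report = MetricsReport.from_predictions(
        y, clf.predict(X), scores=clf.decision_scores(X),
        convergence=getattr(clf, "convergence_", None),
        split_descriptor=f"learning_pct={split_info['learning_pct']}",
    )
    report.to_json(out_json)
    roc_csv = out_json.parent / "roc.csv"
    if report.roc_points:
        np.savetxt(roc_csv, np.asarray(report.roc_points), delimiter=",", header="fpr,tpr")
    log.info("evaluate: accuracy %.4f on %d held-out rows", report.accuracy, len(test_idx))
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: dict, outdir) -> MetricsReport:
    """Fused end-to-end run; every intermediate is persisted under
    ``outdir`` and a manifest records versions, seeds and artifact hashes."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = outdir / "raw"
    filtered = outdir / "filtered"
    stage = "synth"
    try:
        run_synth(config, raw)
        stage = "preprocess"
        run_preprocess(config, raw, filtered)
        stage = "features"
        features_csv = run_features(config, filtered, outdir / "features.csv")
        stage = "train"
        run_train(config, features_csv, outdir / "model",
                  augmented_csv=outdir / "augmented.csv")
        stage = "evaluate"
        report = run_evaluate(config, features_csv, outdir / "model", outdir / "metrics.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    artifacts = ["features.csv", "augmented.csv", "metrics.json",
                 "model/weights.csv", "model/network_spec.json"]
    manifest = {
        "version": __version__,
        "seed": config["seed"],
        "stage_seeds": {s: stage_seed(config["seed"], s) for s in STAGES},
        "hashes": {a: _sha256(outdir / a) for a in artifacts if (outdir / a).exists()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
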