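"""Reading and writing ECG records and feature tables.

CSV records: header row, a leading ``time`` column, one column per lead;
sampling rate, label and lead names live in a JSON sidecar next to the CSV
(``<stem>.meta.json``).  WFDB records: PhysioNet-style ``.hea`` header plus
``.dat`` sample file; only the ubiquitous 16-bit little-endian sample format
("format 16", used e.g. by the PTB diagnostic records) is supported.
Feature tables: one row per record, block-wise column names, plus ``label``
and ``augmented`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import ECGRecord, LABELS


class RecordFormatError(ValueError):
    """Malformed record file (header or samples)."""


# ---------------------------------------------------------------------------
# CSV records

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_record_csv(record: ECGRecord, path) -> None:
    path = Path(path)
    if record.n_samples < 1:
        raise ValueError("cannot write an empty record")
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time": t})
    for name, lead in zip(record.lead_names, record.samples):
        df[name] = lead
    df.to_csv(path, index=False)
    meta = {
        "fs": record.fs,
        "lead_names": list(record.lead_names),
        "label": record.label,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_record_csv(path, fs: Optional[float] = None, label: Optional[str] = None) -> ECGRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # ragged rows, bad quoting, ...
        raise RecordFormatError(f"malformed CSV record {path}: {exc}") from exc
    if df.isna().any().any():
        raise RecordFormatError(f"malformed CSV record {path}: ragged or missing values")
    cols = [c for c in df.columns if c != "time"]
    if not cols:
        raise RecordFormatError(f"CSV record {path} has no lead columns")
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        if "time" in df.columns and len(df) > 1:
            dt = float(df["time"].iloc[1] - df["time"].iloc[0])
            fs = 1.0 / dt if dt > 0 else None
    if fs is None:
        raise RecordFormatError(f"sampling rate unavailable for {path}")
    label = label if label is not None else meta.get("label")
    samples = df[cols].to_numpy().T
    if not np.all(np.isfinite(samples)):
        raise RecordFormatError(f"non-finite samples in {path}")
    return ECGRecord(samples=samples, fs=float(fs), lead_names=cols, label=label)


# ---------------------------------------------------------------------------
# WFDB (format 16)

def write_record_wfdb(record: ECGRecord, path) -> None:
    """Write ``<path>.hea`` + ``<path>.dat`` (format 16, gain 1000 ADU/mV)."""
    path = Path(path)
    name = path.name
    gain = 1000.0
    adc = np.round(record.samples * gain).astype("<i2")  # interleaved int16
    dat_name = name + ".dat"
    lines = [f"{name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for li, lead in enumerate(record.lead_names):
        first = int(adc[li, 0])
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    if record.label is not None:
        lines.append(f"# label: {record.label}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    path.with_suffix(".dat").write_bytes(adc.T.reshape(-1).tobytes())


def read_record_wfdb(path) -> ECGRecord:
    """Read a WFDB record given the path of its header (with or without
    the ``.hea`` suffix)."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    label = None
    for ln in lines:
        if ln.startswith("#") and "label:" in ln:
            cand = ln.split("label:", 1)[1].strip()
            if cand in LABELS:
                label = cand
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise RecordFormatError(f"empty WFDB header {hea}")
    head = body[0].split()
    try:
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise RecordFormatError(f"malformed WFDB header line: {body[0]!r}") from exc
    sig_lines = body[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise RecordFormatError(f"WFDB header {hea} declares {n_sig} signals, found {len(sig_lines)}")
    dat_files, gains, baselines, leads = [], [], [], []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        if len(parts) < 2:
            raise RecordFormatError(f"malformed WFDB signal line: {ln!r}")
        dat_files.append(parts[0])
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise RecordFormatError(f"unsupported WFDB sample format {fmt!r} (only 16)")
        gain, baseline = 200.0, 0.0
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = float(b.rstrip(")"))
            if float(g) != 0:
                gain = float(g)
        gains.append(gain)
        baselines.append(baseline)
        leads.append(parts[-1] if len(parts) > 5 else f"S{i}")
    if len(set(dat_files)) != 1:
        raise RecordFormatError("multi-file WFDB records are not supported")
    dat = hea.parent / dat_files[0]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB sample file not found: {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_samples and raw.size != n_samples * n_sig:
        raise RecordFormatError(
            f"WFDB sample file {dat} holds {raw.size} values, expected {n_samples * n_sig}"
        )
    adc = raw.reshape(-1, n_sig).T.astype(float)
    samples = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    return ECGRecord(samples=samples, fs=fs, lead_names=leads, label=label)


# ---------------------------------------------------------------------------
# dispatch

def read_record(path, format: str = "csv", **kwargs) -> ECGRecord:
    if format == "csv":
        return read_record_csv(path, **kwargs)
    if format == "wfdb":
        return read_record_wfdb(path)
    raise ValueError(f"unknown record format {format!r}; expected 'csv' or 'wfdb'")


def write_record(record: ECGRecord, path, format: str = "csv") -> None:
    if format == "csv":
        return write_record_csv(record, path)
    if format == "wfdb":
        return write_record_wfdb(record, path)
    raise ValueError(f"unknown record format {format!r}; expected 'csv' or 'wfdb'")


# ---------------------------------------------------------------------------
# feature tables and manifests

def write_features(feature_set, path) -> None:
    """Write a :class:`~ecgmi.augmentation.LabeledFeatureSet` as CSV,
    preserving the block-layout column order."""
    path = Path(path)
    cols = feature_set.layout.column_names() if feature_set.layout is not None else [
        f"f_{i}" for i in range(feature_set.matrix.shape[1])
    ]
    df = pd.DataFrame(feature_set.matrix, columns=cols)
    df["label"] = feature_set.labels
    df["augmented"] = feature_set.augmented.astype(int)
    df.to_csv(path, index=False)


def read_features(path):
    from .augmentation import LabeledFeatureSet
    from .staticfeat import BlockLayout

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    for col in ("label", "augmented"):
        if col not in df.columns:
            raise RecordFormatError(f"feature table {path} lacks a {col!r} column")
    feat_cols = [c for c in df.columns if c not in ("label", "augmented")]
    layout = BlockLayout.from_column_names(feat_cols)
    return LabeledFeatureSet(
        matrix=df[feat_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        augmented=df["augmented"].to_numpy(dtype=bool),
        layout=layout,
    )


def write_manifest(entries, path) -> None:
    """Dataset manifest: one row per record (id, path, label)."""
    pd.DataFrame(entries, columns=["id", "path", "label"]).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = {"id", "path", "label"} - set(df.columns)
    if missing:
        raise RecordFormatError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df
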