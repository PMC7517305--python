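"""Cohort file formats: per-patient CSV traces and the cohort manifest.

Each patient's ECG is a two-column CSV ``(time_s, ecg_uV)``; the manifest
CSV lists ``patient_id, label, tw_min, fs_hz, path, rosc_time_s`` with paths
relative to the manifest location.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .preprocess import EcgRecord

MANIFEST_COLUMNS = ["patient_id", "label", "tw_min", "fs_hz", "path", "rosc_time_s"]


def write_cohort(records: List[EcgRecord], out_dir: str | Path, tw: float) -> Path:
    """Write per-patient CSVs and the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.patient_id}.csv"
        t = np.arange(rec.samples.size) / rec.fs
        pd.DataFrame({"time_s": t, "ecg_uV": rec.samples}).to_csv(
            out_dir / fname, index=False, float_format="%.3f"
        )
        rows.append({
            "patient_id": rec.patient_id,
            "label": rec.label,
            "tw_min": tw,
            "fs_hz": rec.fs,
            "path": fname,
            "rosc_time_s": rec.rosc_time,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> List[EcgRecord]:
    """Read a cohort manifest and its per-patient CSV traces."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        trace = pd.read_csv(base / row["path"])
        records.append(
            EcgRecord(
                patient_id=str(row["patient_id"]),
                samples=trace["ecg_uV"].to_numpy(dtype=float),
                fs=float(row["fs_hz"]),
                rosc_time=float(row["rosc_time_s"]),
                label=int(row["label"]),
            )
        )
    return records


def write_beat_annotations(path: str | Path, patient_id: str, detector: str,
                           indices: np.ndarray, fs: float) -> None:
    """Append beat annotations as CSV (patient_id, detector, sample_index, time_s)."""
    path = Path(path)
    df = pd.DataFrame({
        "patient_id": patient_id,
        "detector": detector,
        "sample_index": np.asarray(indices, dtype=int),
        "time_s": np.asarray(indices) / fs,
    })
    df.to_csv(path, mode="a", header=not path.exists(), index=False)
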