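"""Readers and writers for the project's plain-text formats.

Trial files are CSV with a ``ch1..ch6`` header and one sample per row;
manifests are TSV (trial_id, gesture, group, sampling_rate_hz, path) with
paths relative to the manifest's directory; feature tables are TSV with
columns ``trial_id, gesture, f01..f48``. All round-trips are lossless at
full floating precision (shortest-round-trip float repr).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import feature_columns
from .synth import N_CHANNELS, Trial

CHANNEL_COLUMNS = [f"ch{i}" for i in range(1, N_CHANNELS + 1)]
MANIFEST_COLUMNS = ["trial_id", "gesture", "group", "sampling_rate_hz", "path"]


def write_trial_csv(trial: Trial, path: str | Path) -> None:
    df = pd.DataFrame(trial.signal.T, columns=CHANNEL_COLUMNS)
    df.to_csv(path, index=False)


def read_trial_csv(path: str | Path, trial_id: str = "",
                   gesture: str = "", sampling_rate: float = 1000.0) -> Trial:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) != N_CHANNELS:
            raise ValueError(
                f"{path}: expected {N_CHANNELS} columns, got {len(header)} "
                f"(line 1)")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(",")
            if len(cells) != N_CHANNELS:
                raise ValueError(
                    f"{path}: expected {N_CHANNELS} columns, got "
                    f"{len(cells)} (line {lineno})")
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell (line {lineno})") from None
    if not rows:
        raise ValueError(f"{path}: no samples")
    signal = np.asarray(rows, dtype=float).T
    return Trial(trial_id or path.stem, gesture, signal, sampling_rate)


def write_dataset(trials: Sequence[Trial], manifest: pd.DataFrame,
                  out_dir: str | Path) -> Path:
    """Write per-trial CSVs plus the TSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "trials").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for trial, (_, row) in zip(trials, manifest.iterrows()):
        if trial.trial_id != row["trial_id"]:
            raise ValueError("trials and manifest rows are out of order")
        write_trial_csv(trial, out_dir / row["path"])
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    return df


def read_dataset(manifest_path: str | Path) -> tuple[list[Trial], pd.DataFrame]:
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    trials = [
        read_trial_csv(base / row["path"], trial_id=row["trial_id"],
                       gesture=row["gesture"],
                       sampling_rate=float(row["sampling_rate_hz"]))
        for _, row in manifest.iterrows()
    ]
    return trials, manifest


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["trial_id", "gesture", *feature_columns(df)]
    df[cols].to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read a labeled feature TSV; reorders columns canonically.

    In strict mode a non-canonical column order is rejected instead.
    """
    df = pd.read_csv(path, sep="\t")
    if "gesture" not in df.columns or "trial_id" not in df.columns:
        raise ValueError(f"{path}: feature table needs trial_id and gesture "
                         f"label columns")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty feature table")
    fcols = feature_columns(df)
    if not fcols:
        raise ValueError(f"{path}: no feature columns f01..")
    canonical = ["trial_id", "gesture", *sorted(fcols)]
    if list(df.columns) != canonical:
        if strict:
            raise ValueError(f"{path}: columns not in canonical order")
        df = df[canonical]
    return df
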