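"""Readers and writers for cohort manifests, ROI series, and model artifacts.

All tabular data is TSV; models, PCA transforms, and partitions are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import CommunityPartition
from .hmm import VBGaussianHMM
from .preprocessing import CohortPCA, SubjectSeries

MANIFEST_COLUMNS = ("subject_id", "group", "site", "age", "fiq", "mean_fd", "path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Validated cohort manifest: one row per subject."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest column(s): {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_id: {dup.iloc[0]!r}")
    for col in ("age", "fiq", "mean_fd"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be numeric")
        if df[col].isna().any():
            raise ValueError(f"{path}: column {col!r} has missing values")
    return df


def read_series(path: str | Path, row: pd.Series | None = None) -> SubjectSeries:
    """One subject's T x R TSV with a header row of ROI labels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in series file ({exc})") from exc
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite value in series file")
    meta = row if row is not None else pd.Series(
        {"subject_id": path.stem, "group": "unknown", "site": "unknown",
         "age": np.nan, "fiq": np.nan, "mean_fd": np.nan}
    )
    return SubjectSeries(
        subject_id=str(meta["subject_id"]), group=str(meta["group"]),
        site=str(meta["site"]), age=float(meta["age"]), fiq=float(meta["fiq"]),
        mean_fd=float(meta["mean_fd"]), data=data, roi_labels=list(df.columns),
    )


def write_series(series: SubjectSeries, path: str | Path) -> None:
    pd.DataFrame(series.data, columns=series.roi_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def load_cohort(manifest_path: str | Path) -> tuple[list[SubjectSeries], pd.DataFrame]:
    """Read the manifest and every subject's series, in manifest order."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        subjects.append(read_series(p, row))
    return subjects, manifest


def save_model(model: VBGaussianHMM, path: str | Path) -> None:
    payload = {
        "n_states": model.n_states,
        "means": model.means_.tolist(),
        "covariances": model.covariances_.tolist(),
        "transmat": model.transmat_.tolist(),
        "startprob": model.startprob_.tolist(),
        "free_energy_trace": model.free_energy_trace_.tolist(),
        "params": model.get_params(),
        "best_restart": int(model.best_restart_),
    }
    Path(path).write_text(json.dumps(payload))


def save_pca(transform: CohortPCA, path: str | Path) -> None:
    payload = {
        "center": transform.center_.tolist(),
        "loadings": transform.loadings_.tolist(),
        "explained_variance_ratio": transform.explained_variance_ratio_.tolist(),
        "n_components": int(transform.n_components_),
    }
    Path(path).write_text(json.dumps(payload))


def load_pca(path: str | Path) -> CohortPCA:
    payload = json.loads(Path(path).read_text())
    t = CohortPCA(n_components=payload["n_components"])
    t.center_ = np.array(payload["center"])
    t.loadings_ = np.array(payload["loadings"])
    t.explained_variance_ratio_ = np.array(payload["explained_variance_ratio"])
    t.n_components_ = payload["n_components"]
    return t


def save_partition(partition: CommunityPartition, path: str | Path) -> None:
    payload = {
        "module_of": [int(m) for m in partition.module_of],
        "Q": float(partition.Q),
        "module_labels": partition.module_labels,
    }
    Path(path).write_text(json.dumps(payload))
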