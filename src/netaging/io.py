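"""Readers/writers for the pipeline's plain-text formats.

Square TSV (ROI header row + first column) for connectivity matrices,
TSV (ROIs x volumes) for session time series, CSV for the cohort table,
JSON for ground truth and manifests. Readers validate strictly: symmetry to
1e-8, matching row/column headers, no duplicate ROI names, required cohort
columns present and nothing unknown.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "write_matrix", "read_matrix",
    "write_timeseries", "read_timeseries",
    "write_cohort", "read_cohort",
    "write_json", "read_json",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ("subject_id", "sex", "cohort", "group", "timepoint_label",
                  "age_days", "session_id")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def write_matrix(path, matrix, roi_names: Sequence[str] | None = None) -> None:
    """Square TSV with ROI names as both header row and first column."""
    if isinstance(matrix, ConnectivityMatrix):
        values, roi_names = matrix.values, matrix.roi_names
    else:
        values = np.asarray(matrix, float)
        if roi_names is None:
            raise ValueError("roi_names required for a bare array")
    df = pd.DataFrame(values, index=list(roi_names), columns=list(roi_names))
    df.to_csv(path, sep="\t", index_label="roi")


def read_matrix(path, symmetry_tol: float = 1e-8) -> ConnectivityMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except Exception as e:
        raise FormatError(f"{path}: cannot parse as matrix TSV ({e})") from e
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise FormatError(f"{path}: duplicate ROI names")
    if rows != cols:
        raise FormatError(f"{path}: header row and first column disagree "
                          "(transposed or reordered file?)")
    values = df.to_numpy(float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(f"{path}: non-finite value at row {bad[0] + 2}")
    if np.abs(values - values.T).max() > symmetry_tol:
        raise FormatError(f"{path}: matrix asymmetric beyond {symmetry_tol}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, roi_names=rows)


def write_timeseries(path, ts: np.ndarray, roi_names: Sequence[str]) -> None:
    """ROIs x volumes TSV; ROI names in the first column."""
    ts = np.asarray(ts, float)
    cols = [f"t{j + 1:04d}" for j in range(ts.shape[1])]
    pd.DataFrame(ts, index=list(roi_names), columns=cols).to_csv(
        path, sep="\t", index_label="roi")


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except Exception as e:
        raise FormatError(f"{path}: cannot parse as time-series TSV ({e})") from e
    values = df.to_numpy(float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(f"{path}: non-finite value at row {bad[0] + 2}, "
                          f"column {bad[1] + 2}")
    return values, [str(r) for r in df.index]


def write_cohort(path, cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort table missing column {missing[0]!r}")
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing column {missing[0]!r}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown column {unknown[0]!r}")
    return df


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
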