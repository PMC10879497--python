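"""Subject-level Fisher-z connectivity matrices and group edge statistics.

Connectivity is the Pearson correlation between ROI time series, Fisher
r-to-z transformed into a symmetric matrix Z (diagonal stored as 0 and
excluded from all statistics); Z+ keeps the positive edges only. Subjects
scanned in more than one session get the element-wise session average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: |r| at or beyond this bound is clipped before atanh (which diverges at 1)
R_CLIP = 1.0 - 1e-7

__all__ = [
    "ConnectivityMatrix",
    "GroupEdgeResult",
    "pearson_matrix",
    "fisher_z",
    "average_sessions",
    "positive_part",
    "group_edge_test",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix for one subject/time point."""

    values: np.ndarray
    roi_names: tuple[str, ...]
    subject_id: str | None = None
    timepoint_label: str | None = None
    n_sessions_averaged: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        n = len(self.roi_names)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match "
                             f"{n} ROI names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric (1e-12)")
        if np.abs(np.diagonal(v)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be stored as 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


def pearson_matrix(timeseries: np.ndarray,
                   roi_names: Sequence[str] | None = None) -> np.ndarray:
    """ROI-by-ROI Pearson correlation of an (n_rois, n_volumes) array."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-d (ROIs x volumes)")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 volumes to correlate")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = roi_names[bad[0]] if roi_names is not None else f"index {bad[0]}"
        raise ValueError(f"ROI {name} has zero variance; correlation undefined")
    r = np.corrcoef(ts)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray, roi_names: Sequence[str] | None = None,
             subject_id: str | None = None,
             timepoint_label: str | None = None) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = atanh(r), off-diagonal; diagonal set to 0.

    |r| >= 1 - 1e-7 is clipped to the bound before the transform (duplicated
    series would otherwise send the edge to infinity); the clipped-edge count
    is logged.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if roi_names is None:
        roi_names = [f"ROI{i + 1:02d}" for i in range(n)]
    off = ~np.eye(n, dtype=bool)
    n_clipped = int(np.sum(np.abs(r[off]) >= R_CLIP)) // 2
    if n_clipped:
        log.warning("fisher_z: clipped %d edge(s) at |r| = %g", n_clipped, R_CLIP)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, roi_names=roi_names,
                              subject_id=subject_id,
                              timepoint_label=timepoint_label)


def average_sessions(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean over a subject's session matrices."""
    if len(matrices) == 0:
        raise ValueError("no matrices to average")
    first = matrices[0]
    if len(matrices) == 1:
        return first
    for m in matrices[1:]:
        if m.roi_names != first.roi_names:
            raise ValueError("session matrices have mismatched ROI sets")
        if (m.subject_id, m.timepoint_label) != (first.subject_id,
                                                 first.timepoint_label):
            raise ValueError("session matrices belong to different "
                             "subject/time point")
    mean = np.mean([m.values for m in matrices], axis=0)
    return replace(first, values=mean, n_sessions_averaged=len(matrices))


def positive_part(Z: ConnectivityMatrix) -> ConnectivityMatrix:
    """Z+ : negative edges replaced by 0, positive edges unchanged."""
    return replace(Z, values=np.where(Z.values > 0, Z.values, 0.0))


@dataclass(frozen=True)
class GroupEdgeResult:
    """Edge-wise one-sample test of mean z against zero across subjects."""

    roi_names: tuple[str, ...]
    mean_z: np.ndarray
    t: np.ndarray
    p: np.ndarray
    neglog10_p: np.ndarray
    q: np.ndarray
    significant: np.ndarray   # q < alpha on unique edges, symmetrised
    alpha: float
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        n = len(self.roi_names)
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "roi_i": [self.roi_names[i] for i in iu],
            "roi_j": [self.roi_names[j] for j in ju],
            "mean_z": self.mean_z[iu, ju],
            "t": self.t[iu, ju],
            "p": self.p[iu, ju],
            "q": self.q[iu, ju],
            "significant": self.significant[iu, ju],
        })


def group_edge_test(Zs: Sequence[ConnectivityMatrix],
                    alpha: float = 0.05) -> GroupEdgeResult:
    """Per-edge mean z, one-sample t against 0, one-sided (upper-tail) p and
    Benjamini-Hochberg q over the n(n-1)/2 unique edges.

    Edges with zero across-subject variance are degenerate: p = 0 when the
    mean is positive, 1 otherwise, with a warning.
    """
    if len(Zs) < 3:
        raise ValueError("group edge test needs >= 3 subjects")
    first = Zs[0]
    for m in Zs[1:]:
        if m.roi_names != first.roi_names:
            raise ValueError("subjects have mismatched ROI sets")
    stack = np.stack([m.values for m in Zs])
    ns = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(ns))
    p = stats.t.sf(t, df=ns - 1)
    # tolerance absorbs accumulation error when all subjects share one value
    degen = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    np.fill_diagonal(degen, False)
    if degen.any():
        warnings.warn(f"{int(degen.sum()) // 2} edge(s) have zero "
                      "across-subject variance; p set degenerately")
        p = np.where(degen, np.where(mean > 0, 0.0, 1.0), p)
        t = np.where(degen, np.where(mean > 0, np.inf, -np.inf), t)
    np.fill_diagonal(p, np.nan)
    np.fill_diagonal(t, 0.0)

    n = mean.shape[0]
    iu = np.triu_indices(n, k=1)
    rej, qvec, _, _ = multipletests(p[iu], alpha=alpha, method="fdr_bh")
    q = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    q[iu] = qvec
    sig[iu] = rej
    q = np.where(np.isnan(q), q.T, q)
    sig = sig | sig.T
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return GroupEdgeResult(roi_names=first.roi_names, mean_z=mean, t=t, p=p,
                           neglog10_p=nlp, q=q, significant=sig, alpha=alpha,
                           n_subjects=ns)
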