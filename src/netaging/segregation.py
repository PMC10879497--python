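"""Network segregation index (SI) and the low-SI exclusion rule.

SI = (mean within-module connectivity - mean between-module connectivity)
     / mean within-module connectivity,

computed from positive Fisher-z edges only, each unique node pair counted
once. SI3 restricts the computation to the three most reliable modules
(subgraph restriction: between-module pairs must span two of the selected
modules; edges to excluded modules are ignored). Later time points reuse the
module partition obtained at baseline (12 months), so the within/between
edge sets are fixed across age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import Partition
from .connectivity import ConnectivityMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SegregationResult",
    "segregation_index",
    "si_trajectories",
    "segregation_table",
    "flag_low_si",
]


@dataclass(frozen=True)
class SegregationResult:
    """SI for one matrix/partition (optionally restricted to a module subset)."""

    si: float
    mean_within: float
    mean_between: float
    n_edges_within: int
    n_edges_between: int
    module_subset: tuple[int, ...] | None
    defined: bool
    subject_id: str | None = None
    timepoint_label: str | None = None
    age_days: float | None = None


def _as_values(Z) -> np.ndarray:
    return Z.values if isinstance(Z, ConnectivityMatrix) else np.asarray(Z, float)


def segregation_index(Z, partition: Partition | np.ndarray,
                      module_subset: Sequence[int] | None = None,
                      negative_policy: str = "exclude") -> SegregationResult:
    """Segregation index of one connectivity matrix under one partition.

    negative_policy:
      * "exclude" (default): non-positive z are dropped from both means
        (edge counts reflect positive edges used);
      * "zero": every pair enters its mean, with non-positive z as 0.

    A between mean with no positive edges is treated as 0, giving SI = 1.
    No positive within edges makes the SI undefined: the row is flagged
    (``defined=False``, si = nan), never silently dropped.
    """
    if negative_policy not in ("exclude", "zero"):
        raise ValueError("negative_policy must be 'exclude' or 'zero'")
    V = _as_values(Z)
    labels = partition.labels if isinstance(partition, Partition) \
        else np.asarray(partition)
    if labels.size != V.shape[0]:
        raise ValueError("partition does not cover the matrix's nodes")
    iu, ju = np.triu_indices(V.shape[0], k=1)
    li, lj = labels[iu], labels[ju]
    if module_subset is not None:
        subset = tuple(int(m) for m in module_subset)
        keep = np.isin(li, subset) & np.isin(lj, subset)
        iu, ju, li, lj = iu[keep], ju[keep], li[keep], lj[keep]
    else:
        subset = None
    vals = V[iu, ju]
    within = li == lj

    def _mean(x: np.ndarray) -> tuple[float, int]:
        if negative_policy == "exclude":
            pos = x[x > 0]
            return (float(pos.mean()) if pos.size else 0.0, int(pos.size))
        return (float(np.clip(x, 0.0, None).mean()) if x.size else 0.0,
                int(np.sum(x > 0)))

    mw, nw = _mean(vals[within])
    mb, nb = _mean(vals[~within])
    if mw <= 0.0 or nw == 0:
        log.warning("segregation_index: no positive within-module edges; "
                    "SI undefined")
        return SegregationResult(si=float("nan"), mean_within=mw,
                                 mean_between=mb, n_edges_within=nw,
                                 n_edges_between=nb, module_subset=subset,
                                 defined=False)
    si = (mw - mb) / mw
    return SegregationResult(si=float(si), mean_within=mw, mean_between=mb,
                             n_edges_within=nw, n_edges_between=nb,
                             module_subset=subset, defined=True)


def si_trajectories(Zs: Mapping[tuple[str, str], ConnectivityMatrix],
                    baseline_partition: Partition | np.ndarray,
                    module_subset: Sequence[int] | None = None,
                    cohort: pd.DataFrame | None = None,
                    negative_policy: str = "exclude") -> pd.DataFrame:
    """SI at every (subject, time point) using the fixed baseline partition.

    ``Zs`` maps (subject_id, timepoint_label) to the averaged connectivity
    matrix; rows are joined to the cohort table (subject metadata, exact age)
    when one is given.
    """
    rows = []
    for (sid, tp), Z in Zs.items():
        res = segregation_index(Z, baseline_partition, module_subset,
                                negative_policy)
        rows.append(dict(subject_id=sid, timepoint_label=tp, si=res.si,
                         mean_within=res.mean_within,
                         mean_between=res.mean_between,
                         n_edges_within=res.n_edges_within,
                         n_edges_between=res.n_edges_between,
                         defined=res.defined))
    out = pd.DataFrame(rows)
    if cohort is not None:
        meta = cohort.drop_duplicates(["subject_id", "timepoint_label"])[
            ["subject_id", "timepoint_label", "sex", "cohort", "group",
             "age_days"]]
        out = out.merge(meta, on=["subject_id", "timepoint_label"], how="left")
    return out


def segregation_table(Zs: Mapping[tuple[str, str], ConnectivityMatrix],
                      baseline_partition: Partition | np.ndarray,
                      module_subset3: Sequence[int],
                      cohort: pd.DataFrame | None = None,
                      threshold: float = 0.43,
                      flag_timepoints: Sequence[str] = ("12mo", "18mo"),
                      negative_policy: str = "exclude") -> pd.DataFrame:
    """Long table with both the all-module SI and the three-module SI3 per
    (subject, time point), plus the low-SI3 exclusion flag."""
    si_all = si_trajectories(Zs, baseline_partition, None, cohort,
                             negative_policy)
    si3 = si_trajectories(Zs, baseline_partition, module_subset3, None,
                          negative_policy)
    out = si_all.rename(columns={"si": "si_all"})
    out = out.merge(
        si3[["subject_id", "timepoint_label", "si"]].rename(
            columns={"si": "si3"}),
        on=["subject_id", "timepoint_label"])
    out["excluded"] = flag_low_si(out, threshold=threshold,
                                  timepoints=flag_timepoints)
    return out


def flag_low_si(table: pd.DataFrame, threshold: float = 0.43,
                timepoints: Sequence[str] = ("12mo", "18mo"),
                column: str = "si3") -> pd.Series:
    """Exclusion flag: a subject is flagged when its SI3 is strictly below
    ``threshold`` at ALL of the listed time points it has (subjects missing a
    listed time point are judged on what exists). Flagged subjects are kept
    in the table; downstream statistics drop them via this flag.
    """
    if column not in table.columns:
        raise ValueError(f"column {column!r} missing from table")
    flagged = {}
    for sid, grp in table.groupby("subject_id"):
        at = grp[grp["timepoint_label"].isin(list(timepoints))]
        flagged[sid] = bool(len(at) > 0 and (at[column] < threshold).all())
    return table["subject_id"].map(flagged)
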