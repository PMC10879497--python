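"""End-to-end orchestration: simulate -> connectivity -> modules ->
segregation -> metrics -> stats, with a YAML-round-trippable config and a
run manifest.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually (and the CLI exposes them as
subcommands). All randomness flows from the single master seed in the
config; a rerun with identical config and seed reproduces every numeric
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import community, graph_metrics, io, models, segregation
from .cohort import CohortSpec, simulate_cohort
from .connectivity import (average_sessions, fisher_z, group_edge_test,
                           pearson_matrix, positive_part)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline",
           "stage_simulate", "stage_connectivity", "stage_modules",
           "stage_segregation", "stage_metrics", "stage_stats"]


@dataclass(frozen=True)
class RunConfig:
    """Run-level options; ``cohort`` holds CohortSpec overrides for
    simulate mode."""

    out_dir: str
    seed: int
    mode: str = "simulate"              # simulate | timeseries | matrices
    input_dir: str | None = None        # for timeseries/matrices modes
    cohort: dict = field(default_factory=dict)
    gammas: tuple[float, ...] = tuple(community.default_gamma_grid().tolist())
    n_reps: int = 1000
    consensus_reps: int = 100
    densities: tuple[float, ...] = tuple(
        graph_metrics.default_density_grid().tolist())
    si_threshold: float = 0.43
    si_flag_timepoints: tuple[str, ...] = ("12mo", "18mo")
    baseline_timepoint: str = "12mo"
    n_si3_modules: int = 3
    fdr_alpha: float = 0.05
    sigma_nulls: int = 10
    edgewise_stats: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "timeseries", "matrices"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate" and not self.input_dir:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if len(self.gammas) < 2:
            raise ValueError("gamma grid needs >= 2 values")
        if any(not (0 < d <= 1) for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("gammas", "densities", "si_flag_timepoints"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        for key in ("cohorts", "timepoints_days", "sexes"):
            if key in kw:
                kw[key] = tuple(tuple(x) if isinstance(x, list) else x
                                for x in kw[key])
        kw.setdefault("seed", self.seed)
        return CohortSpec(**kw)

    def run_dir(self) -> Path:
        return Path(self.out_dir)


def _seed(cfg: RunConfig, stage: int) -> int:
    return int(np.random.SeedSequence([int(cfg.seed), stage]).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig) -> dict:
    cfg.validate()
    out = cfg.run_dir()
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    spec = cfg.cohort_spec()
    sim = simulate_cohort(spec)
    io.write_cohort(out / "cohort.csv", sim.design)
    io.write_json(out / "ground_truth.json", dict(
        partition=sim.truth.partition,
        subject_offsets=dict(sim.truth.subject_offsets),
        table=sim.truth.table.to_dict(orient="list")))
    for sid, ts in sim.sessions.items():
        io.write_timeseries(out / "sessions" / f"{sid}.tsv", ts,
                            spec.roi_names)
    return {"n_sessions": len(sim.sessions), "n_rows": len(sim.design),
            "n_subjects": sim.design["subject_id"].nunique()}


def _load_subject_matrices(cfg: RunConfig):
    out = cfg.run_dir()
    cohort = io.read_cohort(out / "cohort.csv")
    mats = {}
    for (sid, tp), grp in cohort.groupby(["subject_id", "timepoint_label"],
                                         sort=False):
        sessions = []
        for s in grp["session_id"]:
            ts, roi = io.read_timeseries(out / "sessions" / f"{s}.tsv")
            sessions.append(fisher_z(pearson_matrix(ts, roi), roi,
                                     subject_id=sid, timepoint_label=tp))
        mats[(sid, tp)] = average_sessions(sessions)
    return cohort, mats


def stage_connectivity(cfg: RunConfig) -> dict:
    """Subject Z matrices (TSV) + per-time-point group edge tests (CSV)."""
    out = cfg.run_dir()
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    if cfg.mode == "matrices":
        raise NotImplementedError(
            "matrices mode: place precomputed Z TSVs under matrices/ and "
            "start from the modules stage")
    cohort, mats = _load_subject_matrices(cfg)
    for (sid, tp), Z in mats.items():
        io.write_matrix(out / "matrices" / f"{sid}_{tp}.tsv", Z)
    frames = []
    for tp, grp in cohort.drop_duplicates(
            ["subject_id", "timepoint_label"]).groupby("timepoint_label"):
        subs = [mats[(sid, tp)] for sid in grp["subject_id"]]
        if len(subs) >= 3:
            res = group_edge_test(subs, alpha=cfg.fdr_alpha)
            f = res.to_frame()
            f.insert(0, "timepoint_label", tp)
            frames.append(f)
    if frames:
        pd.concat(frames).to_csv(out / "group_edge_tests.csv", index=False)
    return {"n_matrices": len(mats)}


def _read_matrices(cfg: RunConfig):
    out = cfg.run_dir()
    cohort = io.read_cohort(out / "cohort.csv")
    mats = {}
    for sid, tp in cohort.drop_duplicates(["subject_id", "timepoint_label"])[
            ["subject_id", "timepoint_label"]].itertuples(index=False):
        m = io.read_matrix(out / "matrices" / f"{sid}_{tp}.tsv")
        mats[(sid, tp)] = dataclasses.replace(m, subject_id=sid,
                                              timepoint_label=tp)
    return cohort, mats


def stage_modules(cfg: RunConfig) -> dict:
    """Gamma sweep at baseline; per-time-point group partitions at the
    selected gamma; classification consistency; module flow table."""
    out = cfg.run_dir()
    (out / "modules").mkdir(parents=True, exist_ok=True)
    cohort, mats = _read_matrices(cfg)
    roi_names = next(iter(mats.values())).roi_names
    seed = _seed(cfg, 3)

    base_ids = sorted({sid for (sid, tp) in mats if tp == cfg.baseline_timepoint})
    base = [positive_part(mats[(sid, cfg.baseline_timepoint)]).values
            for sid in base_ids]
    sweep = community.gamma_sweep(base, gammas=cfg.gammas, n_reps=cfg.n_reps,
                                  seed=seed, consensus_reps=cfg.consensus_reps)
    sel = sweep.selected_partition
    pd.DataFrame({"roi": roi_names, "module": sel.labels}).to_csv(
        out / "modules" / "baseline_partition.tsv", sep="\t", index=False)
    sweep.nmi_table.to_csv(out / "modules" / "nmi_table.csv")

    # classification consistency of the baseline consensus, from fresh reps
    # pooled over baseline subjects at the selected gamma
    reps = []
    for i, W in enumerate(base):
        reps.extend(community.repeated_partitions(
            W, gamma=sweep.selected_gamma,
            n_reps=max(cfg.consensus_reps, 10), seed=seed + 7919 + i))
    consistency = community.classification_consistency(reps, sel)
    pd.DataFrame({"roi": roi_names, "consistency": consistency}).to_csv(
        out / "modules" / "classification_consistency.csv", index=False)
    si3_modules = community.most_consistent_modules(consistency, sel,
                                                    k=cfg.n_si3_modules)

    # per-time-point group partitions at the selected gamma + flow table
    tps = list(dict.fromkeys(cohort["timepoint_label"]))
    parts = {}
    for ti, tp in enumerate(tps):
        ids = sorted({sid for (sid, t) in mats if t == tp})
        Ws = [positive_part(mats[(sid, tp)]).values for sid in ids]
        subj_parts = []
        for si, W in enumerate(Ws):
            cons, _ = community.subject_consensus(
                W, gamma=sweep.selected_gamma, n_reps=cfg.n_reps,
                seed=seed + 104729 * (ti + 1) + si)
            subj_parts.append(cons)
        parts[tp] = community.group_consensus(
            subj_parts, gamma=sweep.selected_gamma,
            seed=seed + 104729 * (ti + 1) + len(Ws),
            n_reps=cfg.consensus_reps)
        pd.DataFrame({"roi": roi_names, "module": parts[tp].labels}).to_csv(
            out / "modules" / f"partition_{tp}.tsv", sep="\t", index=False)
    flow = community.match_modules_across_timepoints(
        [(tp, parts[tp]) for tp in tps])
    flow.to_csv(out / "modules" / "module_flow.csv", index=False)

    io.write_json(out / "modules" / "summary.json", dict(
        selected_gamma=sweep.selected_gamma,
        mean_nmi={str(k): v for k, v in sweep.mean_nmi.items()},
        n_modules=sel.n_modules, si3_modules=si3_modules,
        failed_gammas=sweep.failed_gammas))
    return {"selected_gamma": sweep.selected_gamma,
            "n_modules": sel.n_modules, "si3_modules": si3_modules}


def _baseline_partition(cfg: RunConfig):
    out = cfg.run_dir()
    part = pd.read_csv(out / "modules" / "baseline_partition.tsv", sep="\t")
    summary = io.read_json(out / "modules" / "summary.json")
    labels = part["module"].to_numpy()
    return (community.Partition(labels=labels,
                                gamma=float(summary["selected_gamma"]),
                                level="group-consensus"),
            [int(m) for m in summary["si3_modules"]])


def stage_segregation(cfg: RunConfig) -> dict:
    out = cfg.run_dir()
    cohort, mats = _read_matrices(cfg)
    baseline, si3_modules = _baseline_partition(cfg)
    table = segregation.segregation_table(
        mats, baseline, si3_modules, cohort=cohort,
        threshold=cfg.si_threshold, flag_timepoints=cfg.si_flag_timepoints)
    table.to_csv(out / "segregation.csv", index=False)
    return {"n_rows": len(table), "n_excluded":
            int(table.drop_duplicates("subject_id")["excluded"].sum())}


def stage_metrics(cfg: RunConfig) -> dict:
    out = cfg.run_dir()
    cohort, mats = _read_matrices(cfg)
    roi_names = list(next(iter(mats.values())).roi_names)
    zps = {k: positive_part(m).values for k, m in mats.items()}
    tab = graph_metrics.metric_table(zps, roi_names,
                                     densities=cfg.densities, cohort=cohort,
                                     sigma_nulls=cfg.sigma_nulls,
                                     seed=_seed(cfg, 5))
    tab.to_csv(out / "metrics.csv", index=False)
    bilat = graph_metrics.combine_bilateral(tab, roi_names)
    bilat.to_csv(out / "metrics_bilateral.csv", index=False)
    return {"n_rows": len(tab)}


def stage_stats(cfg: RunConfig) -> dict:
    out = cfg.run_dir()
    (out / "stats").mkdir(parents=True, exist_ok=True)
    seg = pd.read_csv(out / "segregation.csv")
    si_report = models.si_trajectory_analysis(seg, outcome="si3")
    si_report.to_csv(out / "stats" / "si3_lme.csv", index=False)
    si_all = models.si_trajectory_analysis(seg, outcome="si_all")
    si_all.to_csv(out / "stats" / "si_all_lme.csv", index=False)

    excluded = set(seg.loc[seg["excluded"].astype(bool), "subject_id"])
    metrics = pd.read_csv(out / "metrics.csv")
    metrics = metrics[~metrics["subject_id"].isin(excluded)]
    gl = metrics[metrics["scope"] == "global"]
    frames = []
    for factor in ("sex", "group"):
        res = models.mass_univariate_lme(
            gl, unit_col="metric", factor=factor, term="age",
            alpha=cfg.fdr_alpha)
        res.insert(0, "factor", factor)
        res.insert(1, "term", "age")
        inter = models.mass_univariate_lme(
            gl, unit_col="metric", factor=factor,
            term=f"age:{factor}[{'M' if factor == 'sex' else 'Y'}]",
            alpha=cfg.fdr_alpha)
        inter.insert(0, "factor", factor)
        inter.insert(1, "term", "age_interaction")
        frames.append(pd.concat([res, inter]))
    pd.concat(frames).to_csv(out / "stats" / "global_metric_lme.csv")

    bilat = pd.read_csv(out / "metrics_bilateral.csv")
    bilat = bilat[~bilat["subject_id"].isin(excluded)]
    nodal_frames = []
    for metric, grp in bilat.groupby("metric"):
        res = models.mass_univariate_lme(grp, unit_col="region", term="age",
                                         alpha=cfg.fdr_alpha)
        res.insert(0, "metric", metric)
        nodal_frames.append(res)
    pd.concat(nodal_frames).to_csv(out / "stats" / "nodal_lme.csv")

    manifest: dict = {"n_si_rows": len(seg)}
    if cfg.edgewise_stats and "group" in seg.columns:
        manifest.update(_edgewise_stats(cfg, out, excluded))
    return manifest


def _edgewise_stats(cfg: RunConfig, out: Path, excluded: set) -> dict:
    """Edge-wise age slopes within the SI3 subgraph, per trajectory group,
    with a KS comparison of the slope distributions."""
    cohort, mats = _read_matrices(cfg)
    baseline, si3_modules = _baseline_partition(cfg)
    keep_nodes = np.flatnonzero(np.isin(baseline.labels, si3_modules))
    roi = list(next(iter(mats.values())).roi_names)
    rows = []
    for (sid, tp), m in mats.items():
        if sid in excluded:
            continue
        for a in range(len(keep_nodes)):
            for b in range(a + 1, len(keep_nodes)):
                i, j = keep_nodes[a], keep_nodes[b]
                rows.append(dict(subject_id=sid, timepoint_label=tp,
                                 edge=f"{roi[i]}|{roi[j]}",
                                 value=m.values[i, j]))
    edges = pd.DataFrame(rows).merge(
        cohort.drop_duplicates(["subject_id", "timepoint_label"])[
            ["subject_id", "timepoint_label", "age_days", "group"]],
        on=["subject_id", "timepoint_label"])
    slopes = {}
    for g, grp in edges.groupby("group"):
        res = models.mass_univariate_lme(grp, unit_col="edge", term="age",
                                         alpha=cfg.fdr_alpha)
        res.to_csv(out / "stats" / f"edgewise_lme_{g}.csv")
        slopes[g] = res["estimate"].dropna().to_numpy()
    result = {}
    if len(slopes) == 2:
        (ga, sa), (gb, sb) = sorted(slopes.items())
        ks, p = models.ks_compare(sa, sb)
        io.write_json(out / "stats" / "edgewise_ks.json",
                      dict(groups=[ga, gb], ks_statistic=ks, p=p))
        result["edgewise_ks"] = ks
    return result


_STAGES = [("simulate", stage_simulate),
           ("connectivity", stage_connectivity),
           ("modules", stage_modules),
           ("segregation", stage_segregation),
           ("metrics", stage_metrics),
           ("stats", stage_stats)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; persists a manifest with config hash and
    per-stage summaries. A stage failure aborts with the stage name while
    prior outputs remain on disk."""
    cfg.validate()
    out = cfg.run_dir()
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "versions": _versions(), "stages": {}}
    for name, fn in _STAGES:
        if name == "simulate" and cfg.mode != "simulate":
            continue
        try:
            manifest["stages"][name] = fn(cfg)
        except Exception as e:
            manifest["stages"][name] = {"error": str(e)}
            io.write_json(out / "manifest.json", manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    io.write_json(out / "manifest.json", manifest)
    return manifest


def _versions() -> dict:
    import networkx
    import scipy
    import statsmodels
    from . import __version__
    return {"netaging": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__}
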