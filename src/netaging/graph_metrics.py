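"""Density-thresholded binary graphs and global/nodal graph metrics.

Z+ matrices are proportionally (density-) thresholded: every subject's graph
keeps the same fraction of strongest unique edges, so group comparisons see
equal edge counts. Metrics are computed per density on a default sweep of 16
values from 0.10 to 0.25 and averaged over the sweep.

Global metrics: clustering coefficient, characteristic path length (CPL),
local efficiency, small-world sigma, Louvain modularity (gamma = 1),
assortativity. Nodal metrics: degree, betweenness (unnormalised, endpoints
excluded), nodal efficiency, clustering coefficient. Undefined values (e.g.
assortativity of a degree-regular graph) are flagged as NaN and excluded
from threshold averaging with their count recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .community import louvain_once, finetune

log = logging.getLogger(__name__)

__all__ = [
    "BinaryGraph",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "density_threshold",
    "default_density_grid",
    "threshold_sweep",
    "global_metrics",
    "nodal_metrics",
    "average_over_thresholds",
    "metric_table",
    "combine_bilateral",
]

GLOBAL_METRICS = ("clustering_coefficient", "characteristic_path_length",
                  "local_efficiency", "small_world_index", "modularity",
                  "assortativity")
NODAL_METRICS = ("degree_centrality", "betweenness_centrality",
                 "nodal_efficiency", "clustering_coefficient")


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted undirected graph from density thresholding."""

    adjacency: np.ndarray
    density: float
    connected: bool

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        object.__setattr__(self, "adjacency", A.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


def density_threshold(Zp: np.ndarray, density: float) -> BinaryGraph:
    """Keep the ceil(density * n(n-1)/2) strongest unique positive edges.

    Ties at the cutoff are broken by ascending (i, j) index, so the edge set
    is deterministic.
    """
    Zp = np.asarray(Zp, dtype=float)
    n = Zp.shape[0]
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    if Zp.min() < 0:
        raise ValueError("density thresholding expects a non-negative Z+ matrix")
    e_max = n * (n - 1) // 2
    n_edges = int(np.ceil(density * e_max))
    iu, ju = np.triu_indices(n, k=1)
    w = Zp[iu, ju]
    pos = w > 0
    if n_edges > int(pos.sum()):
        raise ValueError(
            f"density {density} requests {n_edges} edges but only "
            f"{int(pos.sum())} positive entries are available")
    # stable sort on (-w, i, j): lexsort keys listed minor-to-major
    order = np.lexsort((ju, iu, -w))[:n_edges]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[order], ju[order]] = 1
    A |= A.T
    n_comp, _ = connected_components(A, directed=False)
    return BinaryGraph(adjacency=A, density=n_edges / e_max,
                       connected=(n_comp == 1))


def default_density_grid() -> np.ndarray:
    """16 evenly spaced densities from 0.10 to 0.25 (step 0.01)."""
    return np.round(np.linspace(0.10, 0.25, 16), 10)


def threshold_sweep(Zp: np.ndarray,
                    densities: Sequence[float] | None = None) -> list[BinaryGraph]:
    """One binary graph per density; edge sets are nested along the sweep."""
    ds = default_density_grid() if densities is None else np.asarray(densities, float)
    if np.any(np.diff(ds) <= 0):
        raise ValueError("densities must be ascending")
    return [density_threshold(Zp, float(d)) for d in ds]


def _distance_matrix(A: np.ndarray) -> np.ndarray:
    return shortest_path(A.astype(float), method="D", unweighted=True)


def _cpl(D: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path length over connected ordered pairs."""
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    conn = bool(finite.sum() == n * (n - 1))
    if not finite.any():
        return float("nan"), conn
    return float(D[finite].mean()), conn


def _nodal_efficiency(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def _small_world_sigma(G: nx.Graph, C: float, L: float, n_rand: int = 10,
                       seed: int = 0) -> float:
    """sigma = (C/C_rand)/(L/L_rand) against degree-preserving rewired nulls
    (double-edge-swap, ``n_rand`` replicates)."""
    rng = np.random.default_rng(seed)
    Cs, Ls = [], []
    n_swap = max(5 * G.number_of_edges(), 1)
    for _ in range(n_rand):
        R = G.copy()
        try:
            nx.double_edge_swap(R, nswap=n_swap, max_tries=n_swap * 50,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXException:
            pass   # un-swappable degree sequence; use graph as-is
        Cs.append(nx.average_clustering(R))
        Lr, _ = _cpl(_distance_matrix(nx.to_numpy_array(R)))
        Ls.append(Lr)
    C_rand = float(np.mean(Cs))
    L_rand = float(np.nanmean(Ls))
    if C_rand <= 0 or L_rand <= 0 or not np.isfinite(L) or C <= 0:
        return float("nan")
    return (C / C_rand) / (L / L_rand)


def _louvain_modularity(A: np.ndarray, n_restarts: int = 10,
                        seed: int = 0) -> float:
    """Best Q over seeded fine-tuned Louvain restarts at gamma = 1."""
    W = A.astype(float)
    seeds = np.random.SeedSequence(int(seed)).generate_state(n_restarts)
    best = -np.inf
    for s in seeds:
        p = finetune(W, louvain_once(W, gamma=1.0, seed=int(s)))
        best = max(best, p.modularity_q)
    return float(best)


def global_metrics(G: BinaryGraph, sigma_nulls: int = 10,
                   modularity_restarts: int = 10,
                   seed: int = 0) -> dict[str, float]:
    """The six global metrics of one binary graph; undefined values are NaN."""
    A = G.adjacency.astype(float)
    if not A.any():
        raise ValueError("empty graph")
    g = G.to_networkx()
    D = _distance_matrix(A)
    C = float(nx.average_clustering(g))
    L, connected = _cpl(D)
    if not connected:
        log.warning("graph disconnected at density %.3f; CPL over connected "
                    "pairs only", G.density)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            assort = float(nx.degree_assortativity_coefficient(g))
        except (ValueError, ZeroDivisionError):
            assort = float("nan")
    if not np.isfinite(assort):
        assort = float("nan")
    return {
        "clustering_coefficient": C,
        "characteristic_path_length": L,
        "local_efficiency": float(nx.local_efficiency(g)),
        "small_world_index": _small_world_sigma(g, C, L, n_rand=sigma_nulls,
                                                seed=seed),
        "modularity": _louvain_modularity(G.adjacency,
                                          n_restarts=modularity_restarts,
                                          seed=seed),
        "assortativity": assort,
    }


def nodal_metrics(G: BinaryGraph) -> pd.DataFrame:
    """Per-node degree, betweenness (unnormalised, endpoints excluded),
    nodal efficiency and clustering coefficient."""
    g = G.to_networkx()
    D = _distance_matrix(G.adjacency.astype(float))
    bt = nx.betweenness_centrality(g, normalized=False)
    cl = nx.clustering(g)
    n = G.n_nodes
    return pd.DataFrame({
        "degree_centrality": G.adjacency.sum(axis=1).astype(float),
        "betweenness_centrality": [bt[i] for i in range(n)],
        "nodal_efficiency": _nodal_efficiency(D),
        "clustering_coefficient": [cl[i] for i in range(n)],
    })


def average_over_thresholds(values: Sequence[float]) -> tuple[float, int]:
    """Arithmetic mean over densities where the metric is defined (non-NaN);
    returns (mean, count). All-undefined -> (nan, 0)."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan"), 0
    return float(v[ok].mean()), int(ok.sum())


def metric_table(Zps: Mapping[tuple[str, str], np.ndarray],
                 roi_names: Sequence[str],
                 densities: Sequence[float] | None = None,
                 cohort: pd.DataFrame | None = None,
                 sigma_nulls: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Long table of threshold-averaged global and nodal metrics.

    ``Zps`` maps (subject_id, timepoint_label) to a Z+ matrix. Columns:
    subject_id, timepoint_label, scope (global|node), metric, region (ROI
    name or '' for globals), value, n_thresholds.
    """
    ds = default_density_grid() if densities is None else np.asarray(densities, float)
    rows = []
    for (sid, tp), Zp in Zps.items():
        graphs = threshold_sweep(Zp, ds)
        gvals = {m: [] for m in GLOBAL_METRICS}
        nvals = {m: [] for m in NODAL_METRICS}
        for gi, G in enumerate(graphs):
            gm = global_metrics(G, sigma_nulls=sigma_nulls,
                                seed=seed + 1000 * gi)
            for m in GLOBAL_METRICS:
                gvals[m].append(gm[m])
            nm = nodal_metrics(G)
            for m in NODAL_METRICS:
                nvals[m].append(nm[m].to_numpy())
        for m in GLOBAL_METRICS:
            val, cnt = average_over_thresholds(gvals[m])
            rows.append(dict(subject_id=sid, timepoint_label=tp,
                             scope="global", metric=m, region="",
                             value=val, n_thresholds=cnt))
        for m in NODAL_METRICS:
            stack = np.stack(nvals[m])   # densities x nodes
            for ni, roi in enumerate(roi_names):
                val, cnt = average_over_thresholds(stack[:, ni])
                rows.append(dict(subject_id=sid, timepoint_label=tp,
                                 scope="node", metric=m, region=roi,
                                 value=val, n_thresholds=cnt))
    out = pd.DataFrame(rows)
    if cohort is not None:
        meta = cohort.drop_duplicates(["subject_id", "timepoint_label"])[
            ["subject_id", "timepoint_label", "sex", "cohort", "group",
             "age_days"]]
        out = out.merge(meta, on=["subject_id", "timepoint_label"], how="left")
    return out


def _pair_regions(roi_names: Sequence[str]) -> dict[str, list[str]]:
    stems: dict[str, list[str]] = {}
    for name in roi_names:
        if name.endswith(("_L", "_R")):
            stems.setdefault(name[:-2], []).append(name)
        else:
            stems.setdefault(name, []).append(name)
    return stems


def combine_bilateral(nodal_table: pd.DataFrame,
                      roi_names: Sequence[str]) -> pd.DataFrame:
    """Mean of the left/right hemispheric values per region.

    ROI names ending in _L/_R are paired on their stem; unpaired ROIs pass
    through unaveraged with a warning.
    """
    stems = _pair_regions(roi_names)
    unpaired = [s for s, members in stems.items() if len(members) != 2]
    if unpaired:
        warnings.warn(f"{len(unpaired)} region(s) lack an L/R partner and "
                      f"pass through unaveraged: {unpaired[:5]}")
    region_of = {m: s for s, members in stems.items() for m in members}
    tab = nodal_table[nodal_table["scope"] == "node"].copy()
    tab["region_pair"] = tab["region"].map(region_of)
    keys = [c for c in ("subject_id", "timepoint_label", "metric", "sex",
                        "cohort", "group", "age_days") if c in tab.columns]
    out = (tab.groupby(keys + ["region_pair"], as_index=False, sort=False)
              .agg(value=("value", "mean"),
                   n_thresholds=("n_thresholds", "min")))
    return out.rename(columns={"region_pair": "region"})
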