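"""Consensus Louvain module detection.

The detection pipeline mirrors the standard resting-state consensus scheme:
many fine-tuned Louvain runs per connectivity matrix, a co-assignment
(agreement) matrix over the runs, iterated re-clustering of the agreement
matrix until a unanimous partition emerges, the same agreement/consensus step
across subjects for a group partition, a gamma sweep with NMI-based selection
of the most representative resolution, per-node classification consistency,
and module-flow matching across time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components

from ._louvain import aggregate, local_move, q_value

__all__ = [
    "Partition",
    "AgreementMatrix",
    "GammaSweepResult",
    "ConvergenceError",
    "louvain_once",
    "finetune",
    "repeated_partitions",
    "agreement_matrix",
    "consensus_partition",
    "subject_consensus",
    "group_consensus",
    "nmi",
    "gamma_sweep",
    "classification_consistency",
    "most_consistent_modules",
    "match_modules_across_timepoints",
    "default_gamma_grid",
]


class ConvergenceError(RuntimeError):
    """Raised when consensus re-clustering fails to reach a unanimous partition."""


def default_gamma_grid() -> np.ndarray:
    """Resolution grid 1.0..2.0 in increments of 0.1 (11 values)."""
    return np.round(np.arange(10, 21) / 10.0, 10)


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel modules 1..k, ordered by descending size then lowest node index."""
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    order = sorted(
        uniq,
        key=lambda u: (-int(np.sum(raw == u)), int(np.argmax(raw == u))),
    )
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in raw], dtype=np.int64)


@dataclass(frozen=True)
class Partition:
    """A node -> module labelling with contiguous labels 1..k."""

    labels: np.ndarray
    gamma: float = 1.0
    level: str = "single-run"   # single-run | subject-consensus | group-consensus
    modularity_q: float = float("nan")

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d array")
        uniq = np.unique(labels)
        if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("module labels must be contiguous integers 1..k")

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules + 1)[1:]


@dataclass(frozen=True)
class AgreementMatrix:
    """Fraction of repetitions co-assigning each node pair to one module."""

    values: np.ndarray
    n_repetitions: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("agreement matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("agreement matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("agreement entries must lie in [0, 1]")


def _validate_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if W.min() < 0:
        raise ValueError("weight matrix must be non-negative")
    W = np.ascontiguousarray((W + W.T) / 2.0)
    np.fill_diagonal(W, 0.0)
    if not np.any(W > 0):
        raise ValueError("empty graph: no positive edge weight")
    return W


def louvain_once(W: np.ndarray, gamma: float = 1.0, seed: int = 0) -> Partition:
    """One greedy two-phase Louvain run at resolution ``gamma``.

    Node sweep order is randomised by ``seed`` (fresh permutation per
    aggregation level); only Q-improving moves are accepted, so the returned
    Q is at least that of the all-singletons partition (which has Q <= 0 at
    gamma >= 0 ... it is the starting point).
    """
    W = _validate_weights(W)
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    node_labels = np.arange(n, dtype=np.int64)
    Wc = W.copy()
    while True:
        nc = Wc.shape[0]
        labels = np.arange(nc, dtype=np.int64)
        order = rng.permutation(nc).astype(np.int64)
        improved = local_move(Wc, float(gamma), labels, order)
        uniq, comp = np.unique(labels, return_inverse=True)
        node_labels = comp.astype(np.int64)[node_labels]
        if not improved or uniq.size == nc or uniq.size == 1:
            break
        Wc = aggregate(Wc, comp.astype(np.int64), uniq.size)
    q = q_value(W, node_labels, float(gamma))
    return Partition(labels=canonical_labels(node_labels), gamma=float(gamma),
                     level="single-run", modularity_q=float(q))


def finetune(W: np.ndarray, partition: Partition, gamma: float | None = None) -> Partition:
    """Iterative modularity fine-tuning: single-node reassignments on the
    full graph until no move improves Q. Output Q >= input Q."""
    W = _validate_weights(W)
    g = partition.gamma if gamma is None else float(gamma)
    labels = (partition.labels - 1).astype(np.int64).copy()
    order = np.arange(W.shape[0], dtype=np.int64)
    local_move(W, g, labels, order)
    q = q_value(W, labels, g)
    return Partition(labels=canonical_labels(labels), gamma=g,
                     level=partition.level, modularity_q=float(q))


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    # counter-based: one uint32 stream state word per repetition
    return np.random.SeedSequence(int(seed)).generate_state(n)


def repeated_partitions(W: np.ndarray, gamma: float, n_reps: int = 1000,
                        seed: int = 0) -> list[Partition]:
    """``n_reps`` independent fine-tuned Louvain runs, reproducible from
    the master seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = _rep_seeds(seed, n_reps)
    out = []
    for s in seeds:
        p = louvain_once(W, gamma=gamma, seed=int(s))
        out.append(finetune(W, p))
    return out


def agreement_matrix(partitions: Sequence[Partition]) -> AgreementMatrix:
    """Co-assignment fraction D_ij over a list of partitions of one node set."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    n = partitions[0].n_nodes
    D = np.zeros((n, n))
    for p in partitions:
        if p.n_nodes != n:
            raise ValueError("all partitions must cover the same node set")
        lab = p.labels
        D += (lab[:, None] == lab[None, :])
    D /= len(partitions)
    return AgreementMatrix(values=D, n_repetitions=len(partitions))


def _is_binary(D: np.ndarray, tol: float = 1e-12) -> bool:
    return bool(np.all((np.abs(D) < tol) | (np.abs(D - 1.0) < tol)))


def _partition_from_binary(D: np.ndarray, gamma: float, level: str) -> Partition:
    n_comp, comp = connected_components(D >= 0.5, directed=False)
    q = q_value(np.ascontiguousarray(D * (1 - np.eye(D.shape[0]))),
                comp.astype(np.int64), float(gamma))
    return Partition(labels=canonical_labels(comp), gamma=float(gamma),
                     level=level, modularity_q=float(q))


def null_corrected(D: np.ndarray) -> np.ndarray:
    """Subtract the permutation-null expected co-assignment (mean off-diagonal
    agreement) and floor at zero; diagonal zeroed for re-clustering."""
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    expected = float(D[off].mean())
    Dc = np.clip(D - expected, 0.0, None)
    np.fill_diagonal(Dc, 0.0)
    return Dc


def consensus_partition(D: AgreementMatrix | np.ndarray, gamma: float,
                        seed: int = 0, n_reps: int = 100,
                        max_iter: int = 50,
                        level: str = "subject-consensus") -> Partition:
    """Iteratively re-cluster an agreement matrix until it is binary / all
    repetitions agree; returns the unanimous partition.

    Before each re-clustering pass the agreement matrix is null-corrected
    (mean off-diagonal subtracted, floored at 0). The resolution used for
    re-partitioning is the gamma of the originating sweep point.
    """
    Dv = D.values if isinstance(D, AgreementMatrix) else np.asarray(D, dtype=float)
    seeds = _rep_seeds(seed, max_iter)
    for it in range(max_iter):
        if _is_binary(Dv):
            return _partition_from_binary(Dv, gamma, level)
        Dc = null_corrected(Dv)
        if not np.any(Dc > 0):
            raise ConvergenceError(
                "agreement matrix has no above-null co-assignment structure "
                f"(iteration {it}); cannot form a consensus partition")
        reps = repeated_partitions(Dc, gamma=gamma, n_reps=n_reps,
                                   seed=int(seeds[it]))
        first = reps[0].labels
        if all(np.array_equal(first, r.labels) for r in reps[1:]):
            return Partition(labels=first, gamma=float(gamma), level=level,
                             modularity_q=reps[0].modularity_q)
        Dv = agreement_matrix(reps).values
    raise ConvergenceError(
        f"consensus clustering did not converge within {max_iter} iterations "
        f"(gamma={gamma}, last agreement range "
        f"[{Dv.min():.3f}, {Dv.max():.3f}])")


def subject_consensus(W: np.ndarray, gamma: float, n_reps: int = 1000,
                      seed: int = 0) -> tuple[Partition, list[Partition]]:
    """Repeated fine-tuned Louvain on one subject's Z+ matrix followed by
    agreement-matrix consensus. Returns (consensus partition, repetitions)."""
    reps = repeated_partitions(W, gamma=gamma, n_reps=n_reps, seed=seed)
    D = agreement_matrix(reps)
    cons = consensus_partition(D, gamma=gamma, seed=seed + 1, n_reps=n_reps,
                               level="subject-consensus")
    return cons, reps


def group_consensus(subject_partitions: Sequence[Partition], gamma: float,
                    seed: int = 0, n_reps: int = 100) -> Partition:
    """Agreement over subject-specific partitions, re-clustered to a single
    group-level consensus partition."""
    if len(subject_partitions) < 2:
        raise ValueError("group consensus needs >= 2 subjects")
    D = agreement_matrix(subject_partitions)
    return consensus_partition(D, gamma=gamma, seed=seed, n_reps=n_reps,
                               level="group-consensus")


def nmi(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Normalised mutual information, arithmetic-mean normalisation:
    2 I(p1;p2) / (H(p1) + H(p2)). Equals 1 iff identical up to relabelling.

    Zero-entropy convention: if both partitions are single-module (H1+H2=0)
    they are identical up to relabelling, so the result is 1.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.size != b.size:
        raise ValueError("partitions must cover the same node set")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(ct, (ai, bi), 1.0)
    pij = ct / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])))
    h1 = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h2 = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    if h1 + h2 == 0.0:
        return 1.0
    return float(np.clip(2.0 * mi / (h1 + h2), 0.0, 1.0))


@dataclass
class GammaSweepResult:
    """Outcome of a resolution sweep with NMI-based selection."""

    gammas: np.ndarray
    partitions: dict[float, Partition]
    subject_partitions: dict[float, list[Partition]]
    nmi_table: pd.DataFrame
    mean_nmi: pd.Series
    selected_gamma: float
    selected_partition: Partition
    failed_gammas: list[float] = field(default_factory=list)


def gamma_sweep(subject_matrices: Sequence[np.ndarray],
                gammas: Sequence[float] | None = None,
                n_reps: int = 1000, seed: int = 0,
                consensus_reps: int | None = None) -> GammaSweepResult:
    """Full sweep: per gamma, subject-level consensus partitions then a group
    consensus; the selected gamma maximises the mean pairwise NMI between its
    group partition and every other gamma's (ties -> smaller gamma)."""
    if len(subject_matrices) < 2:
        raise ValueError("gamma sweep needs >= 2 subjects")
    gs = default_gamma_grid() if gammas is None else np.asarray(gammas, dtype=float)
    c_reps = n_reps if consensus_reps is None else consensus_reps
    n_subj = len(subject_matrices)
    ss = np.random.SeedSequence(int(seed)).generate_state(len(gs) * (n_subj + 1))
    group_parts: dict[float, Partition] = {}
    subj_parts: dict[float, list[Partition]] = {}
    failed: list[float] = []
    for gi, g in enumerate(gs):
        block = ss[gi * (n_subj + 1):(gi + 1) * (n_subj + 1)]
        try:
            parts = []
            for si, W in enumerate(subject_matrices):
                cons, _ = subject_consensus(W, gamma=float(g), n_reps=n_reps,
                                            seed=int(block[si]))
                parts.append(cons)
            gp = group_consensus(parts, gamma=float(g), seed=int(block[n_subj]),
                                 n_reps=c_reps)
            group_parts[float(g)] = gp
            subj_parts[float(g)] = parts
        except ConvergenceError as e:
            failed.append(float(g))
            warnings.warn(f"gamma={g}: consensus failed ({e}); skipped")
    surv = sorted(group_parts)
    if len(surv) < 2:
        raise ConvergenceError("fewer than 2 gamma values produced a group partition")
    tab = pd.DataFrame(
        [[nmi(group_parts[ga], group_parts[gb]) for gb in surv] for ga in surv],
        index=surv, columns=surv)
    mean_nmi = pd.Series(
        {ga: tab.loc[ga, [gb for gb in surv if gb != ga]].mean() for ga in surv})
    selected = float(mean_nmi.index[int(np.argmax(mean_nmi.values))])
    return GammaSweepResult(
        gammas=gs, partitions=group_parts, subject_partitions=subj_parts,
        nmi_table=tab, mean_nmi=mean_nmi, selected_gamma=selected,
        selected_partition=group_parts[selected], failed_gammas=failed)


def _overlap_mapping(rep: np.ndarray, consensus: np.ndarray) -> dict[int, int]:
    """Match repetition modules to consensus modules by maximal overlap
    (Hungarian assignment on the contingency table)."""
    rmods = np.unique(rep)
    cmods = np.unique(consensus)
    ct = np.zeros((rmods.size, cmods.size))
    for i, rm in enumerate(rmods):
        for j, cm in enumerate(cmods):
            ct[i, j] = np.sum((rep == rm) & (consensus == cm))
    ri, ci = linear_sum_assignment(-ct)
    return {int(rmods[i]): int(cmods[j]) for i, j in zip(ri, ci)}


def classification_consistency(reps: Sequence[Partition],
                               consensus: Partition) -> np.ndarray:
    """Per-node fraction of repetitions in which the node's module (after
    overlap matching) coincides with its consensus module."""
    n = consensus.n_nodes
    correct = np.zeros(n)
    for p in reps:
        if p.n_nodes != n:
            raise ValueError("repetition covers a different node set")
        mapping = _overlap_mapping(p.labels, consensus.labels)
        mapped = np.array([mapping.get(int(l), 0) for l in p.labels])
        correct += (mapped == consensus.labels)
    return correct / len(reps)


def most_consistent_modules(consistency: np.ndarray, partition: Partition,
                            k: int = 3) -> list[int]:
    """The k modules with highest mean per-node classification consistency
    (the 'most reliable' modules; used to restrict the segregation index)."""
    means = {m: float(consistency[partition.members(m)].mean())
             for m in range(1, partition.n_modules + 1)}
    order = sorted(means, key=lambda m: (-means[m], m))
    return order[:k]


def match_modules_across_timepoints(
        partitions_by_timepoint: Mapping[str, Partition] | Sequence[tuple[str, Partition]],
) -> pd.DataFrame:
    """Node-flow table between consecutive time points' partitions.

    One row per (source module, target module) pair sharing nodes, with the
    shared-node count, Jaccard overlap, and a flag marking the dominant
    (maximal-Jaccard) correspondence of each source module.
    """
    items = list(partitions_by_timepoint.items()) \
        if isinstance(partitions_by_timepoint, Mapping) else list(partitions_by_timepoint)
    if len(items) < 2:
        raise ValueError("need partitions at >= 2 time points")
    rows = []
    for (ta, pa), (tb, pb) in zip(items[:-1], items[1:]):
        if pa.n_nodes != pb.n_nodes:
            raise ValueError("partitions must share one node set")
        for ma in range(1, pa.n_modules + 1):
            sa = set(pa.members(ma).tolist())
            jac = {}
            for mb in range(1, pb.n_modules + 1):
                sb = set(pb.members(mb).tolist())
                shared = len(sa & sb)
                if shared:
                    jac[mb] = (shared, shared / len(sa | sb))
            best = max(jac, key=lambda m: (jac[m][1], -m))
            for mb, (shared, j) in sorted(jac.items()):
                rows.append(dict(timepoint_from=ta, timepoint_to=tb,
                                 module_from=ma, module_to=mb,
                                 n_shared=shared, jaccard=j,
                                 dominant=(mb == best)))
    return pd.DataFrame(rows)
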