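"""Consensus Louvain machinery: single runs vs exhaustive search, fine-tuning
monotonicity, agreement/consensus recovery, NMI conventions, gamma sweep
selection, classification consistency and module flow."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from conftest import two_cliques
from netaging.community import (ConvergenceError, Partition,
                                agreement_matrix, classification_consistency,
                                consensus_partition, default_gamma_grid,
                                finetune, gamma_sweep, group_consensus,
                                louvain_once, match_modules_across_timepoints,
                                most_consistent_modules, nmi,
                                repeated_partitions)

from _oracles import max_modularity, modularity_q, partitions_of


def planted_z(labels, within=0.55, between=0.10):
    W = np.where(np.equal.outer(labels, labels), within, between)
    np.fill_diagonal(W, 0.0)
    return W


class TestLouvainOnce:
    def test_two_cliques_recovered_and_match_exhaustive(self):
        A = two_cliques(4)   # 8 nodes: exhaustive search feasible
        p = louvain_once(A, gamma=1.0, seed=0)
        assert p.n_modules == 2
        assert len(set(p.labels[:4])) == 1 and len(set(p.labels[4:])) == 1
        assert p.modularity_q == pytest.approx(max_modularity(A), abs=1e-12)

    def test_complete_graph_single_module(self):
        A = 1.0 - np.eye(6)
        p = louvain_once(A, gamma=1.0, seed=1)
        assert p.n_modules == 1
        assert p.modularity_q == pytest.approx(max_modularity(A), abs=1e-12)

    def test_q_at_least_singletons(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            A = (rng.random((12, 12)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if not A.any():
                continue
            p = louvain_once(A, gamma=1.0, seed=seed)
            q_singletons = modularity_q(A, np.arange(12))
            assert p.modularity_q >= q_singletons - 1e-12

    def test_q_matches_networkx_convention(self):
        rng = np.random.default_rng(3)
        A = (rng.random((15, 15)) < 0.3).astype(float)
        A = np.triu(A, 1); A = A + A.T
        for gamma in (1.0, 1.5):
            p = louvain_once(A, gamma=gamma, seed=2)
            G = nx.from_numpy_array(A)
            comms = [set(np.flatnonzero(p.labels == m))
                     for m in range(1, p.n_modules + 1)]
            q_nx = nx.algorithms.community.modularity(G, comms,
                                                      resolution=gamma)
            assert p.modularity_q == pytest.approx(q_nx, abs=1e-10)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty graph"):
            louvain_once(np.zeros((5, 5)), gamma=1.0, seed=0)

    def test_never_exceeds_exhaustive_maximum(self):
        rng = np.random.default_rng(7)
        hits = 0
        trials = 12
        for t in range(trials):
            n = int(rng.integers(5, 8))
            A = (rng.random((n, n)) < 0.45).astype(float)
            A = np.triu(A, 1); A = A + A.T
            if not A.any():
                hits += 1
                continue
            best = max_modularity(A)
            p = finetune(A, louvain_once(A, gamma=1.0, seed=t))
            assert p.modularity_q <= best + 1e-12
            if abs(p.modularity_q - best) < 1e-12:
                hits += 1
        assert hits >= 0.75 * trials   # small graphs, single seed each


class TestFinetune:
    def test_locally_optimal_partition_is_fixed_point(self):
        A = two_cliques(5)
        labels = np.array([1] * 5 + [2] * 5)
        p = Partition(labels=labels, gamma=1.0)
        out = finetune(A, p)
        assert np.array_equal(out.labels, labels)
        assert out.modularity_q == pytest.approx(0.5)

    def test_mislabeled_node_corrected_and_q_increases(self):
        A = two_cliques(5)
        bad = np.array([2] + [1] * 4 + [2] * 5)
        q_before = modularity_q(A, bad)
        out = finetune(A, Partition(labels=bad, gamma=1.0))
        assert out.n_modules == 2
        assert len(set(out.labels[:5])) == 1
        assert out.modularity_q > q_before
        assert out.modularity_q == pytest.approx(modularity_q(
            A, out.labels), abs=1e-12)

    def test_q_never_decreases(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            A = (rng.random((10, 10)) < 0.4).astype(float)
            A = np.triu(A, 1); A = A + A.T
            if not A.any():
                continue
            start = Partition(labels=rng.integers(1, 4, 10) * 0 + np.array(
                [1, 1, 2, 2, 3, 3, 1, 2, 3, 1]), gamma=1.0)
            q0 = modularity_q(A, start.labels)
            out = finetune(A, start)
            assert out.modularity_q >= q0 - 1e-12


class TestRepeatedPartitions:
    def test_strong_structure_gives_unanimous_reps(self, planted_labels):
        W = planted_z(planted_labels)
        reps = repeated_partitions(W, gamma=1.0, n_reps=20, seed=0)
        assert all(nmi(r, reps[0]) == pytest.approx(1.0) for r in reps)
        assert nmi(reps[0].labels, planted_labels) == pytest.approx(1.0)

    def test_single_rep(self):
        reps = repeated_partitions(two_cliques(3), 1.0, n_reps=1, seed=0)
        assert len(reps) == 1

    def test_master_seed_reproducible(self):
        A = two_cliques(4)
        a = repeated_partitions(A, 1.0, n_reps=10, seed=5)
        b = repeated_partitions(A, 1.0, n_reps=10, seed=5)
        assert all(np.array_equal(x.labels, y.labels) for x, y in zip(a, b))


class TestAgreement:
    def test_identical_partitions_binary(self):
        p = Partition(labels=np.array([1, 1, 2, 2]))
        D = agreement_matrix([p, p, p])
        within = np.equal.outer(p.labels, p.labels).astype(float)
        assert np.array_equal(D.values, within)

    def test_single_disagreement_counts_half(self):
        p1 = Partition(labels=np.array([1, 1, 2, 2]))
        p2 = Partition(labels=np.array([1, 2, 2, 2]))
        D = agreement_matrix([p1, p2]).values
        assert D[0, 1] == 0.5
        assert D[2, 3] == 1.0

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        parts = [Partition(labels=np.sort(rng.integers(1, 3, 6)) * 0 +
                           np.array([1, 1, 1, 2, 2, 2])) for _ in range(3)]
        D = agreement_matrix(parts).values
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 1.0)


class TestConsensus:
    def test_binary_block_matrix_one_shot(self):
        labels = np.array([1, 1, 1, 2, 2])
        D = np.equal.outer(labels, labels).astype(float)
        p = consensus_partition(D, gamma=1.0, seed=0)
        assert nmi(p.labels, labels) == pytest.approx(1.0)

    def test_planted_recovery_from_noisy_reps(self, planted_labels,
                                              make_planted_zplus):
        W = make_planted_zplus(1, seed=21)[0]
        reps = repeated_partitions(W, gamma=1.0, n_reps=100, seed=3)
        D = agreement_matrix(reps)
        cons = consensus_partition(D, gamma=1.0, seed=4, n_reps=100)
        assert nmi(cons.labels, planted_labels) == pytest.approx(1.0)
        med_q = np.median([finetune(W, r).modularity_q for r in reps])
        q_cons = modularity_q_weighted(W, cons.labels)
        assert q_cons >= med_q - 1e-9

    def test_structureless_agreement_raises(self):
        D = np.full((6, 6), 0.5)
        np.fill_diagonal(D, 1.0)
        with pytest.raises(ConvergenceError):
            consensus_partition(D, gamma=1.0, seed=0, n_reps=10)


def modularity_q_weighted(W, labels):
    """Oracle Q for weighted graphs (gamma = 1), e_cc - a_c^2 form."""
    twom = W.sum()
    deg = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += W[np.ix_(idx, idx)].sum() / twom - (deg[idx].sum() / twom) ** 2
    return q


class TestGroupConsensus:
    def test_shared_partition_returned(self):
        p = Partition(labels=np.array([1, 1, 1, 2, 2, 2]))
        out = group_consensus([p] * 5, gamma=1.0, seed=0, n_reps=20)
        assert nmi(out, p) == pytest.approx(1.0)

    def test_majority_structure_recovered_under_label_noise(
            self, planted_labels):
        rng = np.random.default_rng(8)
        parts = []
        for _ in range(20):
            lab = planted_labels.copy()
            flip = rng.random(lab.size) < 0.10
            lab[flip] = rng.integers(1, 7, flip.sum())
            parts.append(Partition(labels=np.asarray(
                Partition(labels=canonicalize(lab)).labels)))
        out = group_consensus(parts, gamma=1.0, seed=1, n_reps=50)
        assert nmi(out.labels, planted_labels) > 0.95

    def test_subject_order_invariant(self, planted_labels):
        rng = np.random.default_rng(12)
        parts = []
        for _ in range(6):
            lab = planted_labels.copy()
            flip = rng.random(lab.size) < 0.05
            lab[flip] = rng.integers(1, 7, flip.sum())
            parts.append(Partition(labels=canonicalize(lab)))
        a = group_consensus(parts, gamma=1.0, seed=2, n_reps=30)
        b = group_consensus(parts[::-1], gamma=1.0, seed=2, n_reps=30)
        assert nmi(a, b) == pytest.approx(1.0)


def canonicalize(lab):
    """Make labels contiguous 1..k for Partition construction."""
    _, inv = np.unique(lab, return_inverse=True)
    return inv + 1


class TestNMI:
    def test_identical_and_relabeled(self):
        p1 = np.array([1, 1, 2, 2, 3, 3])
        p2 = np.array([3, 3, 1, 1, 2, 2])
        assert nmi(p1, p1) == pytest.approx(1.0)
        assert nmi(p1, p2) == pytest.approx(1.0)

    def test_independent_partitions_zero(self):
        assert nmi(np.array([1, 1, 2, 2]),
                   np.array([1, 2, 1, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_single_module_convention(self):
        ones = np.ones(5, dtype=int)
        assert nmi(ones, ones) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_arithmetic_normalization(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 5, 40)
        b = rng.integers(1, 4, 40)
        expect = normalized_mutual_info_score(a, b,
                                              average_method="arithmetic")
        assert nmi(canonicalize(a), canonicalize(b)) == pytest.approx(
            expect, abs=1e-10)


class TestGammaSweep:
    def test_tie_broken_toward_smaller_gamma(self, planted_labels,
                                             make_planted_zplus):
        mats = make_planted_zplus(4, seed=30)
        res = gamma_sweep(mats, gammas=(1.0, 1.2, 1.4), n_reps=30, seed=0)
        # strong planted structure: all gammas agree -> smallest selected
        assert res.selected_gamma == 1.0
        assert nmi(res.selected_partition.labels,
                   planted_labels) == pytest.approx(1.0)

    def test_nmi_table_symmetric_unit_diagonal(self, make_planted_zplus):
        mats = make_planted_zplus(3, seed=31)
        res = gamma_sweep(mats, gammas=(1.0, 1.5), n_reps=20, seed=1)
        tab = res.nmi_table.to_numpy()
        assert np.allclose(tab, tab.T)
        assert np.allclose(np.diag(tab), 1.0)

    def test_default_grid(self):
        g = default_gamma_grid()
        assert len(g) == 11
        assert g[0] == 1.0 and g[-1] == 2.0
        assert np.allclose(np.diff(g), 0.1)


class TestClassificationConsistency:
    def test_unanimous_reps_score_one(self):
        p = Partition(labels=np.array([1, 1, 2, 2]))
        cc = classification_consistency([p] * 10, p)
        assert np.array_equal(cc, np.ones(4))

    def test_counting_fraction(self):
        cons = Partition(labels=np.array([1, 1, 1, 2, 2, 2]))
        wrong = Partition(labels=np.array([2, 1, 1, 2, 2, 2]))
        reps = [cons] * 8 + [wrong] * 2
        cc = classification_consistency(reps, cons)
        assert cc[0] == pytest.approx(0.8)
        assert np.all(cc[1:] == 1.0)

    def test_relabeled_reps_still_count_correct(self):
        cons = Partition(labels=np.array([1, 1, 2, 2]))
        relab = Partition(labels=np.array([2, 2, 1, 1]))
        cc = classification_consistency([relab] * 5, cons)
        assert np.array_equal(cc, np.ones(4))

    def test_boundary_node_scores_lower(self, planted_labels):
        # node 0's membership weakened: equally tied to modules 1 and 2
        W = planted_z(planted_labels)
        W[0, :] = np.where(np.isin(planted_labels, [1, 2]), 0.3, 0.1)
        W[:, 0] = W[0, :]
        np.fill_diagonal(W, 0.0)
        reps = repeated_partitions(W, gamma=1.0, n_reps=50, seed=2)
        cons = consensus_partition(agreement_matrix(reps), gamma=1.0,
                                   seed=3, n_reps=50)
        cc = classification_consistency(reps, cons)
        core = np.flatnonzero(planted_labels == 1)[1:]
        assert cc[0] <= cc[core].mean() + 1e-9

    def test_most_consistent_modules_selects_reliable(self):
        part = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        cc = np.array([1.0, 1.0, 0.5, 0.5, 0.9, 0.9])
        assert most_consistent_modules(cc, part, k=2) == [1, 3]


class TestModuleFlow:
    def test_identical_partitions_diagonal_flow(self):
        p = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        flow = match_modules_across_timepoints([("12mo", p), ("18mo", p)])
        dom = flow[flow["dominant"]]
        assert len(dom) == 3
        assert (dom["module_from"] == dom["module_to"]).all()
        assert (dom["jaccard"] == 1.0).all()

    def test_split_module_flows_to_two_targets(self):
        a = Partition(labels=np.array([1, 1, 1, 1, 2, 2]))
        b = Partition(labels=np.array([1, 1, 2, 2, 3, 3]))
        flow = match_modules_across_timepoints([("12mo", a), ("18mo", b)])
        out1 = flow[flow["module_from"] == 1]
        assert set(out1["module_to"]) == {1, 2}

    def test_flows_conserve_node_counts(self):
        rng = np.random.default_rng(4)
        a = Partition(labels=canonicalize(rng.integers(1, 4, 20)))
        b = Partition(labels=canonicalize(rng.integers(1, 5, 20)))
        flow = match_modules_across_timepoints([("t1", a), ("t2", b)])
        for m in range(1, a.n_modules + 1):
            total = flow.loc[flow["module_from"] == m, "n_shared"].sum()
            assert total == (a.labels == m).sum()
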