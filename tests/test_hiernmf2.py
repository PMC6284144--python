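"""Rank-2 NNLS, alternating NMF, split scoring and tree construction."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from hiertweet.hiernmf2 import (
    DegenerateSplitError,
    assign_children,
    flat_clusters,
    hier_cluster,
    nnls_rank2,
    rank2_nmf,
    split_score,
    top_terms,
    tree_to_dict,
)
from hiertweet.synth import default_spec, evaluate_recovery, sample_corpus
from hiertweet.textprep import build_matrix
from hiertweet.corpus import dedupe_unique


# ---------------------------------------------------------------------------
# Brute-force oracle for rank-2 NNLS: exhaustive active-set candidates plus
# grid refinement over the nonnegative quadrant.
# ---------------------------------------------------------------------------

def oracle_nnls_rank2(W, a, grid=60, rounds=4):
    def resid(h):
        return float(np.linalg.norm(W @ h - a))

    candidates = []
    # active-set candidates computed independently (lstsq, per-column)
    h_free, *_ = np.linalg.lstsq(W, a, rcond=None)
    if np.all(h_free >= 0):
        candidates.append(h_free)
    for j in range(2):
        wj = W[:, j]
        denom = float(wj @ wj)
        h = np.zeros(2)
        if denom > 0:
            h[j] = max(0.0, float(wj @ a) / denom)
        candidates.append(h)
    candidates.append(np.zeros(2))
    best = min(candidates, key=resid)

    # grid refinement around the incumbent
    center = np.maximum(best, 0.0)
    width = max(1.0, float(np.abs(center).max())) * 2.0
    for _ in range(rounds):
        g0 = np.linspace(max(0.0, center[0] - width), center[0] + width, grid)
        g1 = np.linspace(max(0.0, center[1] - width), center[1] + width, grid)
        H0, H1 = np.meshgrid(g0, g1)
        R = W @ np.vstack([H0.ravel(), H1.ravel()]) - a[:, None]
        k = int(np.argmin(np.einsum("ij,ij->j", R, R)))
        cand = np.array([H0.ravel()[k], H1.ravel()[k]])
        if resid(cand) < resid(best):
            best = cand
        center = best
        width /= grid / 4.0
    return best


class TestNnlsRank2:
    def test_orthonormal_identity_case(self):
        W = np.eye(4)[:, :2]
        h = nnls_rank2(W, np.array([3.0, 4.0, 0.0, 0.0]))
        np.testing.assert_allclose(h, [3.0, 4.0], atol=1e-12)

    def test_boundary_solution(self):
        W = np.eye(3)[:, :2]
        h = nnls_rank2(W, np.array([0.0, 2.0, 0.0]))
        np.testing.assert_allclose(h, [0.0, 2.0], atol=1e-12)

    def test_negative_component_clipped_to_active_set(self):
        # strongly correlated columns force a negative unconstrained coef
        W = np.array([[1.0, 0.9], [0.0, 0.1], [0.0, 0.1]])
        a = np.array([1.0, -0.0, 0.0])
        h = nnls_rank2(W, a)
        assert np.all(h >= 0)
        oracle = oracle_nnls_rank2(W, a)
        assert np.linalg.norm(W @ h - a) <= np.linalg.norm(W @ oracle - a) + 1e-10

    def test_matches_oracle_on_200_random_instances(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            W = rng.uniform(0, 1, size=(6, 2))
            if rng.random() < 0.3:
                # correlated columns exercise the active-set branches
                W[:, 1] = W[:, 0] * rng.uniform(0.5, 1.5) + 0.01 * rng.uniform(
                    size=6
                )
            a = rng.uniform(0, 1, size=6)
            if rng.random() < 0.2:
                a = W @ rng.uniform(0, 2, size=2)  # exactly representable
            h = nnls_rank2(W, a)
            assert np.all(h >= 0)
            oracle = oracle_nnls_rank2(W, a)
            gap = np.linalg.norm(W @ h - a) - np.linalg.norm(W @ oracle - a)
            worst = max(worst, gap)
        assert worst <= 1e-10

    def test_both_columns_zero_raises(self):
        with pytest.raises(DegenerateSplitError):
            nnls_rank2(np.zeros((4, 2)), np.ones(4))


class TestRank2Nmf:
    def test_exact_rank2_recovered(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0, 1, size=(30, 2))
        H0 = rng.uniform(0, 1, size=(2, 25))
        A = W0 @ H0
        fac = rank2_nmf(A, seed=1, tol=1e-10, max_iter=500)
        rel = np.linalg.norm(A - fac.W @ fac.H) / np.linalg.norm(A)
        assert rel <= 1e-6

    def test_single_repeated_column(self):
        col = np.random.default_rng(3).uniform(0, 1, size=20)
        A = np.tile(col[:, None], (1, 6))
        fac = rank2_nmf(A, seed=2, tol=1e-12, max_iter=300)
        rel = np.linalg.norm(A - fac.W @ fac.H) / np.linalg.norm(A)
        assert rel <= 1e-9

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0, 1, size=(50, 40))
        fac = rank2_nmf(A, seed=5)
        trace = np.asarray(fac.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * trace[0])
        assert trace[-1] <= trace[0] + 1e-8 * trace[0]

    def test_w_columns_unit_norm_nonnegative(self):
        rng = np.random.default_rng(9)
        A = sp.random(40, 30, density=0.3, random_state=1, format="csc")
        fac = rank2_nmf(A, seed=3)
        assert np.all(fac.W >= 0) and np.all(fac.H >= 0)
        norms = np.linalg.norm(fac.W, axis=0)
        for n in norms:
            assert n == pytest.approx(1.0, abs=1e-9) or n == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0, 1, size=(20, 15))
        f1 = rank2_nmf(A, seed=4)
        f2 = rank2_nmf(A, seed=4)
        np.testing.assert_array_equal(f1.W, f2.W)
        np.testing.assert_array_equal(f1.H, f2.H)

    def test_single_document_rejected(self):
        with pytest.raises(DegenerateSplitError):
            rank2_nmf(np.ones((5, 1)), seed=0)


class TestAssignChildren:
    def test_clean_split(self):
        L, R = assign_children(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert list(L) == [0] and list(R) == [1]

    def test_tie_goes_left(self):
        L, R = assign_children(np.array([[0.5], [0.5]]))
        assert list(L) == [0] and list(R) == []

    def test_hand_assigned_four_columns(self):
        H = np.array([[0.9, 0.2, 0.6, 0.1],
                      [0.1, 0.8, 0.2, 0.7]])
        L, R = assign_children(H)
        assert list(L) == [0, 2] and list(R) == [1, 3]


class TestTopTerms:
    def test_ranked_by_weight(self):
        terms = ["t0", "t1", "t2"]
        assert top_terms(np.array([0.9, 0.1, 0.5]), terms, 2) == ["t0", "t2"]

    def test_m_top_beyond_vocab_gives_full_ranking(self):
        terms = ["a", "b"]
        assert top_terms(np.array([0.1, 0.9]), terms, 10) == ["b", "a"]

    def test_ties_broken_by_vocabulary_order(self):
        terms = ["a", "b", "c"]
        assert top_terms(np.array([0.5, 0.5, 0.5]), terms, 3) == ["a", "b", "c"]


class TestSplitScore:
    def test_disjoint_lists_score_one(self):
        assert split_score(["a", "b", "c"], ["d", "e", "f"]) == pytest.approx(1.0)

    def test_identical_lists_score_zero(self):
        assert split_score(["a", "b"], ["a", "b"]) == pytest.approx(0.0)

    def test_hand_computed_shared_rank1(self):
        """m_top = 3, each list contains the sibling's rank-1 term as its
        own rank-1: mNDCG = (1/log2(3) + 1/2) / (1 + 1/log2(3) + 1/2)."""
        left = ["x", "l2", "l3"]
        right = ["x", "r2", "r3"]
        mndcg = (1 / math.log2(3) + 0.5) / (1 + 1 / math.log2(3) + 0.5)
        assert split_score(left, right) == pytest.approx(mndcg**2, abs=1e-12)
        assert split_score(left, right) == pytest.approx(0.2816, abs=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_score(["a"], ["a", "b"])


def _planted_matrix_and_labels(n_docs, seed, **kw):
    spec = default_spec(n_docs=n_docs, seed=seed, **kw)
    corpus, labels = sample_corpus(spec)
    unique, _ = dedupe_unique(corpus)
    tdm = build_matrix(unique)
    by_id = {t.id: l for t, l in zip(corpus.tweets, labels)}
    truth = np.array([by_id[d] for d in tdm.doc_ids])
    return spec, tdm, truth


class TestHierCluster:
    def test_max_leaves_one_root_only(self):
        A = np.random.default_rng(0).uniform(0, 1, size=(10, 8))
        tree = hier_cluster(A, max_leaves=1, min_node_docs=2)
        assert len(tree.nodes) == 1
        assert len(tree.leaves) == 1

    def test_block_diagonal_two_leaves(self):
        # two disjoint vocabularies -> the first split recovers the blocks
        A = np.zeros((8, 12))
        A[:4, :6] = np.random.default_rng(1).uniform(0.5, 1.0, size=(4, 6))
        A[4:, 6:] = np.random.default_rng(2).uniform(0.5, 1.0, size=(4, 6))
        tree = hier_cluster(A, max_leaves=2, min_node_docs=2, seed=0)
        leaves = tree.leaves
        assert len(leaves) == 2
        doc_sets = sorted(
            [sorted(l.doc_indices.tolist()) for l in leaves], key=lambda s: s[0]
        )
        assert doc_sets == [list(range(6)), list(range(6, 12))]

    def test_planted_four_topics_recovered(self):
        spec, tdm, truth = _planted_matrix_and_labels(800, seed=13)
        tree = hier_cluster(tdm, max_leaves=4, min_node_docs=5, seed=13)
        labels = flat_clusters(tree)
        metrics = evaluate_recovery(labels, truth)
        assert metrics["ari"] >= 0.9
        # every planted anchor sits in the top-10 of exactly one leaf
        for topic, anchors in spec.anchor_words.items():
            for anchor in anchors:
                hits = sum(anchor in l.top_terms[:10] for l in tree.leaves)
                assert hits == 1

    def test_flat_clusters_match_leaf_doc_sets(self):
        A = np.random.default_rng(5).uniform(0, 1, size=(15, 30))
        tree = hier_cluster(A, max_leaves=3, min_node_docs=3, seed=2)
        labels = flat_clusters(tree)
        for leaf in tree.leaves:
            assert set(np.flatnonzero(labels == leaf.node_id)) == set(
                leaf.doc_indices
            )

    def test_permuted_columns_same_partition(self):
        # clearly separated blocks: the partition must follow the permutation
        A = np.zeros((8, 12))
        A[:4, :6] = 0.8
        A[4:, 6:] = 0.6
        A += np.random.default_rng(3).uniform(0, 0.01, size=A.shape)
        perm = np.random.default_rng(4).permutation(12)
        t1 = hier_cluster(A, max_leaves=2, min_node_docs=2, seed=1)
        t2 = hier_cluster(A[:, perm], max_leaves=2, min_node_docs=2, seed=1)
        l1 = flat_clusters(t1)[perm]
        l2 = flat_clusters(t2)
        assert evaluate_recovery(l1, l2)["ari"] == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            hier_cluster(np.zeros((0, 0)), max_leaves=2)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        max_leaves=st.integers(1, 6),
        min_node_docs=st.integers(2, 6),
        n_docs=st.integers(10, 40),
        n_terms=st.integers(6, 20),
    )
    def test_tree_invariants_randomized(
        self, seed, max_leaves, min_node_docs, n_docs, n_terms
    ):
        """Binary structure, partitioning, depths and the leaf bound hold
        for arbitrary configurations."""
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(n_terms, n_docs)) * (
            rng.random(size=(n_terms, n_docs)) < 0.5
        )
        A[:, A.sum(axis=0) == 0] = 0.5  # no empty documents
        tree = hier_cluster(
            A, max_leaves=max_leaves, min_node_docs=min_node_docs, seed=seed
        )
        tree.validate()
        assert tree.nodes[tree.root_id].depth == 1
        assert len(tree.leaves) <= max_leaves
        labels = flat_clusters(tree)
        assert np.all(labels >= 0)

    def test_export_dict_counts_match(self):
        A = np.random.default_rng(8).uniform(0, 1, size=(12, 20))
        tree = hier_cluster(A, max_leaves=3, min_node_docs=3, seed=6)
        d = tree_to_dict(tree)
        assert len(d["nodes"]) == len(tree.nodes)
        by_id = {n["node_id"]: n for n in d["nodes"]}
        for nid, node in tree.nodes.items():
            assert by_id[nid]["doc_count"] == node.doc_indices.size
            assert by_id[nid]["depth"] == node.depth
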