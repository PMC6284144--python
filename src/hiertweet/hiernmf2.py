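"""Hierarchical rank-2 NMF binary topic trees.

The clustering core: a term-document matrix A (m terms x n documents,
nonnegative) is recursively bisected.  At each step a rank-2 NMF
A_sub ~= W H (W: m x 2 with unit-norm columns, H: 2 x n_sub, both
nonnegative) is fitted by alternating *exact* rank-2 nonnegative least
squares, documents are assigned to the child whose H row dominates, and a
well-separatedness score based on modified NDCG of the two children's top
term lists decides which frontier leaf to split next.  Splitting stops at
``max_leaves`` leaves or when no leaf can be split without producing a
child smaller than ``min_node_docs`` (such leaves become permanent).  The
result is a binary tree of nonleaf nodes (nln) and leaf nodes (ln); a
node's depth is its "degree level", with the root at level 1.

Because each half-step of the alternation solves its subproblem exactly,
the squared Frobenius objective is non-increasing across iterations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DegenerateSplitError",
    "Rank2Factorization",
    "TopicNode",
    "TopicTree",
    "nnls_rank2",
    "rank2_nmf",
    "assign_children",
    "top_terms",
    "split_score",
    "hier_cluster",
    "flat_clusters",
    "tree_to_dict",
    "tree_to_json",
    "tree_to_dot",
]


class DegenerateSplitError(ValueError):
    """The submatrix cannot support a rank-2 split; the caller should mark
    the node a permanent leaf."""


# ---------------------------------------------------------------------------
# Exact rank-2 nonnegative least squares
# ---------------------------------------------------------------------------

def _nnls_rank2_gram(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min_{h>=0} ||W h - a||_2 for every column a, given the Gram
    matrix G = W^T W (2x2) and B = W^T A (2 x n).

    The exact minimizer is found by checking the three candidate active
    sets: the unconstrained normal-equation solution if it is nonnegative,
    otherwise the better of the two single-column projections
    h_j = max(0, w_j^T a / ||w_j||^2).
    """
    g11, g12, g22 = G[0, 0], G[0, 1], G[1, 1]
    det = g11 * g22 - g12 * g12
    n = B.shape[1]
    H = np.zeros((2, n))

    scale = max(g11, g22)
    if scale <= 0.0:
        raise DegenerateSplitError("both design columns are zero")

    if det > 1e-14 * scale * scale:
        H[0] = (g22 * B[0] - g12 * B[1]) / det
        H[1] = (g11 * B[1] - g12 * B[0]) / det
        bad = (H[0] < 0) | (H[1] < 0)
    else:
        bad = np.ones(n, dtype=bool)

    if bad.any():
        b1, b2 = B[0, bad], B[1, bad]
        c1 = np.maximum(b1 / g11, 0.0) if g11 > 0 else np.zeros_like(b1)
        c2 = np.maximum(b2 / g22, 0.0) if g22 > 0 else np.zeros_like(b2)
        # residual^2 = ||a||^2 - 2 h.b + h^T G h; compare the varying part
        f1 = -2.0 * c1 * b1 + c1 * c1 * g11
        f2 = -2.0 * c2 * b2 + c2 * c2 * g22
        use1 = f1 <= f2
        h1 = np.where(use1, c1, 0.0)
        h2 = np.where(use1, 0.0, c2)
        H[0, bad] = h1
        H[1, bad] = h2
    return H


def nnls_rank2(W: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Exact minimizer of ``||W h - a||_2`` subject to ``h >= 0`` for a
    two-column design ``W``.

    Raises
    ------
    DegenerateSplitError
        If both columns of W are identically zero.
    """
    W = np.asarray(W, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).ravel()
    if W.ndim != 2 or W.shape[1] != 2:
        raise ValueError("W must have exactly 2 columns")
    G = W.T @ W
    B = (W.T @ a).reshape(2, 1)
    return _nnls_rank2_gram(G, B)[:, 0]


# ---------------------------------------------------------------------------
# Alternating rank-2 NMF
# ---------------------------------------------------------------------------

@dataclass
class Rank2Factorization:
    """W (terms x 2, unit-norm columns), H (2 x documents), with the
    per-iteration squared Frobenius residual trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    iterations: int
    converged: bool

    @property
    def relative_residual(self) -> float:
        return self._rel

    _rel: float = field(default=float("nan"), repr=False)


def _objective(normA2: float, WtA: np.ndarray, G: np.ndarray, H: np.ndarray) -> float:
    """||A - W H||_F^2 via the trace expansion (A touched once per call)."""
    term2 = float(np.sum(WtA * H))
    term3 = float(np.sum((G) * (H @ H.T)))
    return max(normA2 - 2.0 * term2 + term3, 0.0)


def rank2_nmf(
    A: sp.spmatrix | np.ndarray,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 200,
    n_restarts: int = 3,
) -> Rank2Factorization:
    """Alternating exact-NNLS rank-2 NMF of a nonnegative matrix.

    W is initialized from two document columns sampled without replacement
    (seeded) plus a small uniform perturbation; ``n_restarts`` independent
    seeded initializations are run and the factorization with the lowest
    final objective is returned (alternating NMF only finds local optima,
    and an initialization drawing both documents from the same latent
    topic can converge to a poor within-topic split).  Each half-step
    solves the column-wise exact rank-2 NNLS subproblem (for H given W on
    the columns of A; for W given H on the rows, via the transposed
    problem).  A run stops when the relative objective decrease falls
    below ``tol`` or after ``max_iter`` iterations.  On return W's columns
    are scaled to unit Euclidean norm with the scale absorbed into H.

    Raises
    ------
    DegenerateSplitError
        If the matrix has fewer than 2 documents or fewer than 2 nonzero
        term rows; callers should mark the corresponding tree node a
        permanent leaf.
    """
    A = sp.csc_matrix(A, dtype=np.float64)
    m, n = A.shape
    if n < 2:
        raise DegenerateSplitError("need at least 2 documents")
    row_nnz = np.asarray((A != 0).sum(axis=1)).ravel()
    if int((row_nnz > 0).sum()) < 2:
        raise DegenerateSplitError("need at least 2 nonzero term rows")
    col_norms = np.sqrt(np.asarray(A.multiply(A).sum(axis=0)).ravel())
    nonzero_cols = np.flatnonzero(col_norms > 0)
    if nonzero_cols.size < 2:
        raise DegenerateSplitError("need at least 2 nonzero documents")

    best: Rank2Factorization | None = None
    for child_seed in np.random.SeedSequence(seed).generate_state(n_restarts):
        fac = _rank2_nmf_once(
            A, nonzero_cols, int(child_seed % (2**31)), tol, max_iter
        )
        if best is None or fac.objective_trace[-1] < best.objective_trace[-1]:
            best = fac
    return best


def _rank2_nmf_once(
    A: sp.csc_matrix,
    nonzero_cols: np.ndarray,
    seed: int,
    tol: float,
    max_iter: int,
) -> Rank2Factorization:
    rng = np.random.default_rng(seed)
    picks = rng.choice(nonzero_cols, size=2, replace=False)
    W = np.asarray(A[:, picks].todense(), dtype=np.float64)
    W = W + 1e-6 * rng.uniform(size=W.shape)

    normA2 = float(A.multiply(A).sum())

    def solve_H(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        G = W.T @ W
        WtA = np.asarray((A.T @ W).T)  # 2 x n
        return _nnls_rank2_gram(G, WtA), G, WtA

    H, G, WtA = solve_H(W)
    trace = [_objective(normA2, WtA, G, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # W update: rows of W solve min_{w>=0} ||A_i. - w H|| with design H^T
        GH = H @ H.T
        HAt = np.asarray((A @ H.T).T)  # 2 x m
        try:
            W = _nnls_rank2_gram(GH, HAt).T
        except DegenerateSplitError:
            break  # one factor vanished entirely; keep previous W
        # rescale columns (product unchanged: compensate in H after solve)
        H, G, WtA = solve_H(W)
        obj = _objective(normA2, WtA, G, H)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj <= tol * max(prev, 1e-300):
            converged = True
            break

    norms = np.linalg.norm(W, axis=0)
    for j in range(2):
        if norms[j] > 0:
            W[:, j] /= norms[j]
            H[j] *= norms[j]
    fac = Rank2Factorization(
        W=W, H=H, objective_trace=trace, iterations=it, converged=converged
    )
    fac._rel = math.sqrt(trace[-1]) / math.sqrt(normA2) if normA2 > 0 else 0.0
    return fac


def assign_children(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition column indices: column j joins the left child L when
    ``H[0, j] >= H[1, j]`` (ties left), else the right child R.  L is the
    child whose topic vector is W's first column."""
    H = np.asarray(H)
    left = H[0] >= H[1]
    return np.flatnonzero(left), np.flatnonzero(~left)


def top_terms(topic_vector: np.ndarray, terms: list[str], m_top: int) -> list[str]:
    """The ``m_top`` terms with the largest weights, descending; ties broken
    by vocabulary order."""
    if m_top < 1:
        raise ValueError("m_top must be >= 1")
    w = np.asarray(topic_vector, dtype=np.float64)
    order = np.lexsort((np.arange(w.size), -w))
    return [terms[i] for i in order[: min(m_top, w.size)]]


def split_score(left_top: list[str], right_top: list[str]) -> float:
    """Well-separatedness of a candidate split in [0, 1].

    For each child's ranked top-term list, a modified NDCG discounts terms
    that also appear in the sibling's list (gain 0) against position
    discounts 1/log2(i+1); the two mNDCG values are multiplied.  Disjoint
    lists score 1, identical lists 0.
    """
    if len(left_top) != len(right_top):
        raise ValueError("top-term lists must have equal length")
    if not left_top:
        raise ValueError("top-term lists must be non-empty")

    def mndcg(ranked: list[str], sibling: set[str]) -> float:
        dcg = 0.0
        idcg = 0.0
        for i, term in enumerate(ranked, start=1):
            disc = 1.0 / math.log2(i + 1)
            idcg += disc
            if term not in sibling:
                dcg += disc
        return dcg / idcg

    return mndcg(left_top, set(right_top)) * mndcg(right_top, set(left_top))


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

@dataclass
class TopicNode:
    """One node of the binary topic tree.

    ``depth`` is the degree level (root = 1).  A leaf has no children; an
    internal node has exactly two (left listed first).  ``split_score`` is
    set on internal nodes (the score their realized split obtained) and on
    permanent leaves it remains None.
    """

    node_id: int
    parent_id: Optional[int]
    child_ids: list[int]
    doc_indices: np.ndarray
    topic_vector: np.ndarray
    top_terms: list[str]
    split_score: Optional[float]
    depth: int
    is_permanent_leaf: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.child_ids


@dataclass
class TopicTree:
    """Binary topic hierarchy over the documents of a term-document matrix."""

    nodes: dict[int, TopicNode]
    root_id: int
    max_leaves: int
    min_node_docs: int
    seed: int
    terms: list[str]

    @property
    def leaves(self) -> list[TopicNode]:
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    def validate(self) -> None:
        """Check structural invariants (binary, partitioning, depths)."""
        root = self.nodes[self.root_id]
        assert root.depth == 1
        for nd in self.nodes.values():
            assert len(nd.child_ids) in (0, 2), "tree must be binary"
            if nd.child_ids:
                l, r = (self.nodes[c] for c in nd.child_ids)
                assert l.depth == nd.depth + 1 and r.depth == nd.depth + 1
                union = np.concatenate([l.doc_indices, r.doc_indices])
                assert len(np.intersect1d(l.doc_indices, r.doc_indices)) == 0
                assert np.array_equal(np.sort(union), np.sort(nd.doc_indices))
        leaf_docs = np.concatenate([l.doc_indices for l in self.leaves])
        assert np.array_equal(np.sort(leaf_docs), np.sort(root.doc_indices))
        assert len(self.leaves) <= self.max_leaves


@dataclass
class _TrialSplit:
    left_docs: np.ndarray
    right_docs: np.ndarray
    W: np.ndarray
    left_top: list[str]
    right_top: list[str]
    score: float


def _node_seed(seed: int, node_id: int) -> int:
    return int(np.random.SeedSequence([seed, node_id]).generate_state(1)[0] % (2**31))


def hier_cluster(
    A,
    max_leaves: int,
    min_node_docs: int = 5,
    m_top: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    m_score: int = 20,
) -> TopicTree:
    """Greedy frontier construction of the binary topic tree.

    Starting from a root holding every document, each current leaf gets a
    trial rank-2 split with its mNDCG separation score; the highest-scoring
    leaf is split (ties to the smaller node id).  A trial producing a child
    with fewer than ``min_node_docs`` documents marks that leaf permanent.
    Stops at ``max_leaves`` leaves or when no splittable leaf remains, so
    the hierarchy is detected automatically and need not be balanced.

    ``m_top`` sets how many ranked terms each node reports; ``m_score``
    sets how many are compared when scoring a candidate split.  Scoring
    needs the longer list: with short lists a rank-2 factorization *within*
    a single coherent topic can still produce disjoint top terms and score
    as well as a genuine two-topic separation, whereas over ~20 terms the
    two halves of one topic share much of their vocabulary and the score
    collapses.

    ``A`` may be a :class:`~hiertweet.textprep.TermDocMatrix` or a raw
    nonnegative sparse/dense matrix (then generic term names are used).
    """
    values, terms = _coerce_matrix(A)
    if max_leaves < 1:
        raise ValueError("max_leaves must be >= 1")
    m, n = values.shape
    if n == 0 or m == 0:
        raise ValueError("empty matrix")

    root_vec = np.asarray(values.sum(axis=1)).ravel()
    root = TopicNode(
        node_id=0,
        parent_id=None,
        child_ids=[],
        doc_indices=np.arange(n),
        topic_vector=root_vec,
        top_terms=top_terms(root_vec, terms, m_top),
        split_score=None,
        depth=1,
    )
    nodes = {0: root}
    trials: dict[int, Optional[_TrialSplit]] = {}
    next_id = 1

    def compute_trial(node: TopicNode) -> Optional[_TrialSplit]:
        docs = node.doc_indices
        if docs.size < 2 or docs.size < 2 * min_node_docs:
            return None
        sub = values[:, docs]
        try:
            fac = rank2_nmf(sub, seed=_node_seed(seed, node.node_id),
                            tol=tol, max_iter=max_iter)
        except DegenerateSplitError:
            return None
        left_loc, right_loc = assign_children(fac.H)
        if left_loc.size < min_node_docs or right_loc.size < min_node_docs:
            return None
        lt = top_terms(fac.W[:, 0], terms, m_top)
        rt = top_terms(fac.W[:, 1], terms, m_top)
        score = split_score(
            top_terms(fac.W[:, 0], terms, m_score),
            top_terms(fac.W[:, 1], terms, m_score),
        )
        return _TrialSplit(
            left_docs=docs[left_loc],
            right_docs=docs[right_loc],
            W=fac.W,
            left_top=lt,
            right_top=rt,
            score=score,
        )

    while True:
        leaves = [nd for nd in nodes.values() if nd.is_leaf]
        if len(leaves) >= max_leaves:
            break
        for leaf in leaves:
            if leaf.node_id not in trials and not leaf.is_permanent_leaf:
                trial = compute_trial(leaf)
                trials[leaf.node_id] = trial
                if trial is None:
                    leaf.is_permanent_leaf = True
        candidates = [
            (trials[l.node_id].score, -l.node_id, l)
            for l in leaves
            if trials.get(l.node_id) is not None
        ]
        if not candidates:
            break
        _, _, best = max(candidates, key=lambda c: (c[0], c[1]))
        trial = trials.pop(best.node_id)
        for side, docs in (("L", trial.left_docs), ("R", trial.right_docs)):
            col = 0 if side == "L" else 1
            child = TopicNode(
                node_id=next_id,
                parent_id=best.node_id,
                child_ids=[],
                doc_indices=docs,
                topic_vector=trial.W[:, col].copy(),
                top_terms=trial.left_top if side == "L" else trial.right_top,
                split_score=None,
                depth=best.depth + 1,
            )
            nodes[next_id] = child
            best.child_ids.append(next_id)
            next_id += 1
        best.split_score = trial.score

    tree = TopicTree(
        nodes=nodes,
        root_id=0,
        max_leaves=max_leaves,
        min_node_docs=min_node_docs,
        seed=seed,
        terms=terms,
    )
    tree.validate()
    return tree


def _coerce_matrix(A) -> tuple[sp.csc_matrix, list[str]]:
    from .textprep import TermDocMatrix

    if isinstance(A, TermDocMatrix):
        return sp.csc_matrix(A.values), list(A.vocabulary.terms)
    values = sp.csc_matrix(A, dtype=np.float64)
    return values, [f"term{i}" for i in range(values.shape[0])]


def flat_clusters(tree: TopicTree) -> np.ndarray:
    """Per-document leaf node id (a flat clustering over all documents)."""
    n = tree.nodes[tree.root_id].doc_indices.size
    labels = np.full(n, -1, dtype=np.int64)
    for leaf in tree.leaves:
        labels[leaf.doc_indices] = leaf.node_id
    return labels


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def tree_to_dict(tree: TopicTree, m_top: int | None = None) -> dict:
    out_nodes = []
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        weights = nd.topic_vector
        order = np.lexsort((np.arange(weights.size), -weights))
        k = len(nd.top_terms) if m_top is None else m_top
        top = [
            {"term": tree.terms[i], "weight": float(weights[i])}
            for i in order[:k]
        ]
        out_nodes.append(
            {
                "node_id": nd.node_id,
                "parent_id": nd.parent_id,
                "child_ids": list(nd.child_ids),
                "depth": nd.depth,
                "doc_count": int(nd.doc_indices.size),
                "top_terms": top,
                "split_score": nd.split_score,
                "is_permanent_leaf": nd.is_permanent_leaf,
            }
        )
    return {
        "root_id": tree.root_id,
        "max_leaves": tree.max_leaves,
        "min_node_docs": tree.min_node_docs,
        "seed": tree.seed,
        "nodes": out_nodes,
    }


def tree_to_json(tree: TopicTree, path, m_top: int | None = None) -> None:
    from pathlib import Path

    Path(path).write_text(
        json.dumps(tree_to_dict(tree, m_top), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def tree_to_dot(tree_dict: dict) -> str:
    """DOT digraph of an exported tree (node id, depth, doc count, terms)."""
    lines = ["digraph topictree {", "  node [shape=box, fontsize=10];"]
    for nd in tree_dict["nodes"]:
        terms = ", ".join(t["term"] for t in nd["top_terms"][:5])
        label = (
            f"n{nd['node_id']} d{nd['depth']} ({nd['doc_count']} docs)\\n{terms}"
        )
        lines.append(f'  n{nd["node_id"]} [label="{label}"];')
    for nd in tree_dict["nodes"]:
        for c in nd["child_ids"]:
            lines.append(f"  n{nd['node_id']} -> n{c};")
    lines.append("}")
    return "\n".join(lines) + "\n"
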