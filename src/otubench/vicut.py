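"""Semi-supervised OTU construction by optimal node-cuts (VI-cut).

Given a dendrogram and taxonomy labels for a subset of the leaves, VI-cut
selects the antichain of tree nodes (a *node-cut*) whose induced clustering
minimizes the Variation of Information to the partial label partition.  The
VI of a node-cut decomposes additively over its chosen nodes,

    VI(A_K, D) = H(D) + sum_{c in K} cost(c),
    cost(c) = -p_c log p_c - 2 sum_j p_cj log(p_cj / (p_c q_j)),

with all fractions computed over labeled leaves only (a cluster without
labeled leaves costs 0), so the optimum is found by a linear-time dynamic
program: best(node) = min(cost(node), best(left) + best(right)), preferring
the node itself on ties (coarser cuts).

Sparsely labeled data would otherwise produce overly general clusters, so
nodes whose leaf set has diameter >= a bound (default 0.07) can be marked
*forbidden*: any chosen cluster containing a forbidden node is subdivided
into the maximal forbidden-free subtrees beneath it, bounding every output
OTU's diameter below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Clustering, MergeTree, cluster_diameter
from .distances import DistanceMatrix
from .vi import vi_to_partial


@dataclass(frozen=True)
class VicutResult:
    node_cut: tuple[int, ...]
    clustering: Clustering
    vi: float


def _label_profiles(tree: MergeTree, labels: dict[str, object]):
    """Per-node label counts among labeled leaves of each subtree."""
    if not labels:
        raise ValueError("VI-cut needs at least one labeled leaf")
    unknown = set(labels) - set(tree.ids)
    if unknown:
        raise ValueError(f"labels refer to ids not in the tree: {sorted(unknown)[:3]}")
    label_names = sorted({str(v) for v in labels.values()})
    lab_idx = {v: k for k, v in enumerate(label_names)}
    n = tree.n_leaves
    counts = np.zeros((tree.n_nodes, len(label_names)))
    for i, sid in enumerate(tree.ids):
        if sid in labels:
            counts[i, lab_idx[str(labels[sid])]] = 1
    for k in range(n - 1):
        l, r = tree.children[k]
        counts[n + k] = counts[l] + counts[r]
    return counts, label_names


def cluster_vi_cost(
    profile: np.ndarray, totals: np.ndarray, n_labeled: int
) -> float:
    """Additive VI contribution of one cluster given its label profile.

    `profile` holds the cluster's per-label counts, `totals` the global label
    counts, `n_labeled` their sum.  A cluster with no labeled leaves
    contributes 0; summing costs over a node-cut and adding H(D) yields the
    exact VI to the partial labeling.
    """
    tot = profile.sum()
    if tot == 0:
        return 0.0
    p_i = tot / n_labeled
    cost = -p_i * np.log(p_i)
    nz = profile > 0
    pij = profile[nz] / n_labeled
    qj = totals[nz] / n_labeled
    cost -= 2.0 * float((pij * np.log(pij / (p_i * qj))).sum())
    return float(cost)


def label_entropy(labels: dict[str, object]) -> float:
    vals = list(labels.values())
    _, counts = np.unique(np.array([str(v) for v in vals]), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def vicut_optimal(tree: MergeTree, labels: dict[str, object]) -> VicutResult:
    """Optimal node-cut minimizing VI to the partial labeling (exact DP)."""
    counts, _ = _label_profiles(tree, labels)
    totals = counts[tree.root]
    n_labeled = int(totals.sum())
    n = tree.n_leaves

    best = np.zeros(tree.n_nodes)
    take = np.ones(tree.n_nodes, dtype=bool)
    for node in range(tree.n_nodes):
        c = cluster_vi_cost(counts[node], totals, n_labeled)
        if node < n:
            best[node] = c
        else:
            l, r = tree.children[node - n]
            s = best[l] + best[r]
            if c <= s + 1e-12:  # prefer the coarser cut on ties
                best[node] = c
            else:
                best[node], take[node] = s, False

    cut: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if take[node]:
            cut.append(node)
        else:
            stack.extend(int(x) for x in tree.children[node - n])

    leaves = tree.leaves_below()
    clustering = Clustering.from_sets(
        [{tree.ids[int(i)] for i in leaves[node]} for node in cut]
    )
    vi = best[tree.root] + label_entropy(labels)
    return VicutResult(tuple(sorted(cut)), clustering, float(max(vi, 0.0)))


def node_diameters(tree: MergeTree, matrix: DistanceMatrix) -> np.ndarray:
    """Diameter (max pairwise distance) of every node's leaf set."""
    pos = matrix.index()
    leaf_pos = np.array([pos[sid] for sid in tree.ids])
    leaves = tree.leaves_below()
    n = tree.n_leaves
    diam = np.zeros(tree.n_nodes)
    V = matrix.values
    for k in range(n - 1):
        l, r = tree.children[k]
        cross = V[np.ix_(leaf_pos[leaves[l]], leaf_pos[leaves[r]])].max()
        diam[n + k] = max(diam[l], diam[r], cross)
    return diam


def mark_forbidden(
    tree: MergeTree, matrix: DistanceMatrix, diameter_threshold: float = 0.07
) -> np.ndarray:
    """Boolean flag per node: True where the subtree diameter >= the bound.

    The comparison is inclusive (a node at exactly the threshold is
    forbidden).  Diameter is monotone up the tree, so ancestors of forbidden
    nodes are forbidden automatically.
    """
    if diameter_threshold <= 0:
        raise ValueError("diameter threshold must be positive")
    return node_diameters(tree, matrix) >= diameter_threshold


def vicut_constrained(
    tree: MergeTree,
    labels: dict[str, object],
    matrix: DistanceMatrix,
    diameter_threshold: float = 0.07,
) -> VicutResult:
    """VI-cut with forbidden nodes: every output OTU diameter < the bound.

    Runs the unconstrained DP first; any chosen cluster containing a
    forbidden node (equivalently, whose own node is forbidden, by
    monotonicity) is replaced by the maximal subtrees beneath it that contain
    no forbidden node.  Leaves are never forbidden, so the refinement always
    terminates with a partition; the result refines the unconstrained
    clustering.
    """
    base = vicut_optimal(tree, labels)
    forbidden = mark_forbidden(tree, matrix, diameter_threshold)
    if not any(forbidden[node] for node in base.node_cut):
        return base

    n = tree.n_leaves
    leaves = tree.leaves_below()
    final_nodes: list[int] = []
    for node in base.node_cut:
        if not forbidden[node]:
            final_nodes.append(node)
            continue
        stack = [node]
        while stack:
            cur = stack.pop()
            if not forbidden[cur]:
                final_nodes.append(cur)
            else:  # forbidden nodes are internal (leaf diameter is 0)
                stack.extend(int(x) for x in tree.children[cur - n])
    clustering = Clustering.from_sets(
        [{tree.ids[int(i)] for i in leaves[node]} for node in final_nodes]
    )
    vi = vi_to_partial(clustering, labels)
    return VicutResult(tuple(sorted(final_nodes)), clustering, vi)


def run_report(
    result: VicutResult, matrix: DistanceMatrix
) -> dict:
    """Summary of one VI-cut run: cluster count, VI to labels, max diameter."""
    max_diam = max(
        cluster_diameter(c, matrix) for c in result.clustering.clusters
    )
    return {
        "n_clusters": result.clustering.n_clusters,
        "vi_to_labels": result.vi,
        "max_diameter": max_diam,
    }
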