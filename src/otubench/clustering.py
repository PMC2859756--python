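"""Agglomerative OTU clustering: nearest, average and furthest neighbor.

The agglomerator follows the classic DOTUR semantics: starting from
singletons, repeatedly merge the two clusters at minimal linkage distance,
where linkage is the minimum (nearest neighbor / single), unweighted
arithmetic mean (average neighbor / UPGMA) or maximum (furthest neighbor /
complete) pairwise distance between members.  OTUs at a threshold D are the
maximal subtrees all of whose merge heights are <= D (inclusive, so zero
-distance duplicates co-cluster at every D >= 0).

Ties in the minimal linkage distance are broken deterministically: among all
candidate pairs, merge the one whose (lexicographically smallest member id,
then the other cluster's smallest member id) sorts first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distances import DistanceMatrix

LINKAGES = ("nearest", "average", "furthest")


@dataclass(frozen=True)
class Clustering:
    """A partition of sequence identifiers into disjoint, non-empty clusters."""

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        total = sum(len(c) for c in self.clusters)
        if total == 0:
            raise ValueError("empty clustering")
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("clusters must be non-empty")
        if len(self.universe) != total:
            raise ValueError("clusters are not disjoint")

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]]) -> "Clustering":
        clusters = sorted(
            (frozenset(s) for s in sets), key=lambda c: min(c)
        )
        return cls(tuple(clusters))

    @classmethod
    def from_labels(cls, labels: dict[str, object]) -> "Clustering":
        groups: dict[object, set[str]] = {}
        for sid, lab in labels.items():
            groups.setdefault(lab, set()).add(sid)
        return cls.from_sets(groups.values())

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)

    def membership(self) -> dict[str, int]:
        return {sid: k for k, c in enumerate(self.clusters) for sid in c}

    def canonical(self) -> frozenset[frozenset[str]]:
        """Membership-only form: two clusterings are equal iff these match."""
        return frozenset(self.clusters)

    def restrict(self, ids: Iterable[str]) -> "Clustering":
        keep = set(ids)
        sets = [c & keep for c in self.clusters if c & keep]
        return Clustering.from_sets(sets)

    def is_refinement_of(self, other: "Clustering") -> bool:
        """True if every cluster here is contained in one cluster of `other`."""
        member = other.membership()
        return all(len({member[s] for s in c}) == 1 for c in self.clusters)


@dataclass(frozen=True)
class MergeTree:
    """Rooted binary dendrogram from agglomerative clustering.

    Nodes 0..n-1 are leaves (in `ids` order); node n+k is the k-th merge.
    `children[k]` holds the two merged nodes and `heights[k]` the linkage
    distance at which they merged.  Heights are non-decreasing for the three
    linkages used here.
    """

    ids: tuple[str, ...]
    children: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def leaves_below(self) -> list[np.ndarray]:
        """Per node, the sorted leaf indices of its subtree."""
        n = self.n_leaves
        out: list[np.ndarray] = [np.array([i]) for i in range(n)]
        for k in range(n - 1):
            l, r = self.children[k]
            out.append(np.sort(np.concatenate([out[l], out[r]])))
        return out

    def representative_leaf(self) -> np.ndarray:
        """Per node, one leaf index inside its subtree (O(n))."""
        rep = np.arange(self.n_nodes)
        n = self.n_leaves
        for k in range(n - 1):
            rep[n + k] = rep[self.children[k][0]]
        return rep

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.heights[node - n])


def agglomerate(matrix: DistanceMatrix, linkage: str = "furthest") -> MergeTree:
    """Build the merge tree under one linkage rule (Lance-Williams updates)."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least two sequences to cluster")
    D = matrix.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    node_of = np.arange(n)  # tree node currently represented by each slot
    rep = list(matrix.ids)  # smallest member id per slot, for tie-breaking
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1, dtype=float)

    for step in range(n - 1):
        dmin = D.min()  # inactive slots hold +inf
        ii, jj = np.where(D == dmin)
        best = None
        for a, b in zip(ii.tolist(), jj.tolist()):
            if a >= b:
                continue
            key = tuple(sorted((rep[a], rep[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, i, j = best

        children[step] = (node_of[i], node_of[j])
        heights[step] = dmin
        # Lance-Williams update into slot i
        others = active.copy()
        others[[i, j]] = False
        idx = np.where(others)[0]
        if linkage == "nearest":
            D[i, idx] = np.minimum(D[i, idx], D[j, idx])
        elif linkage == "furthest":
            D[i, idx] = np.maximum(D[i, idx], D[j, idx])
        else:  # average, unweighted (UPGMA)
            D[i, idx] = (sizes[i] * D[i, idx] + sizes[j] * D[j, idx]) / (
                sizes[i] + sizes[j]
            )
        D[idx, i] = D[i, idx]
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        node_of[i] = n + step
        rep[i] = min(rep[i], rep[j])

    return MergeTree(tuple(matrix.ids), children, heights)


def cut_at_threshold(tree: MergeTree, D: float) -> Clustering:
    """OTUs at threshold D: maximal subtrees with all merge heights <= D."""
    if D < 0:
        raise ValueError("threshold must be non-negative")
    n = tree.n_leaves
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rep = tree.representative_leaf()
    for k in range(n - 1):
        if tree.heights[k] <= D:
            l, r = tree.children[k]
            a, b = find(int(rep[l])), find(int(rep[r]))
            if a != b:
                parent[a] = b
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(tree.ids[i])
    return Clustering.from_sets(groups.values())


def threshold_sweep(
    matrix: DistanceMatrix,
    linkage: str,
    thresholds: Sequence[float],
) -> list[tuple[float, Clustering]]:
    """Cut one merge tree at every threshold (ascending)."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    tree = agglomerate(matrix, linkage)
    return [(float(t), cut_at_threshold(tree, t)) for t in thresholds]


def default_threshold_grid() -> list[float]:
    """The canonical 46-point grid 0.00 .. 0.45 in steps of 0.01."""
    return [round(0.01 * k, 2) for k in range(46)]


def cluster_diameter(cluster: Iterable[str], matrix: DistanceMatrix) -> float:
    """Maximum pairwise distance within the cluster (0 for singletons)."""
    ids = list(cluster)
    if len(ids) < 2:
        return 0.0
    return float(matrix.submatrix(ids).max())


# ---------------------------------------------------------------------------
# interchange


def to_newick(tree: MergeTree) -> str:
    """Newick with ultrametric branch lengths (leaf-to-leaf path = merge height)."""
    n = tree.n_leaves

    def render(node: int, parent_height: float) -> str:
        h = tree.node_height(node)
        bl = (parent_height - h) / 2.0
        if node < n:
            return f"{tree.ids[node]}:{bl:.6f}"
        l, r = tree.children[node - n]
        return f"({render(int(l), h)},{render(int(r), h)}):{bl:.6f}"

    root = tree.root
    h = tree.node_height(root)
    if n == 1:
        return f"{tree.ids[0]}:0.000000;"
    l, r = tree.children[root - n]
    return f"({render(int(l), h)},{render(int(r), h)});"


def write_otu_list(results: list[tuple[float, Clustering]], path) -> None:
    """DOTUR-style list file: threshold, cluster count, comma-joined clusters."""
    with open(path, "w") as fh:
        for D, clustering in results:
            parts = [
                ",".join(sorted(c)) for c in clustering.clusters
            ]
            fh.write(f"{D:.2f}\t{clustering.n_clusters}\t" + "\t".join(parts) + "\n")


def write_membership_tsv(clustering: Clustering, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster_index\n")
        for k, c in enumerate(clustering.clusters):
            for sid in sorted(c):
                fh.write(f"{sid}\t{k}\n")


def read_membership_tsv(path) -> Clustering:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("expected header 'id<TAB>cluster_index'")
        for line in fh:
            if line.strip():
                sid, k = line.rstrip("\n").split("\t")
                labels[sid] = k
    return Clustering.from_labels(labels)
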