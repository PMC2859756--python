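"""Entropy, mutual information and the Variation of Information metric.

For a partition C of m items with cluster sizes m_i, write p_i = m_i / m.
The entropy is H(C) = -sum_i p_i log p_i.  Given a second partition D of the
same items with joint cell fractions p_ij, the mutual information is
I(C, D) = sum_ij p_ij log(p_ij / (p_i q_j)), and the Variation of Information

    VI(C, D) = H(C) + H(D) - 2 I(C, D)

is a true metric on partitions: symmetric, non-negative, zero exactly for
identical partitions, and obeying the triangle inequality.  The natural
logarithm is used by default (base configurable); the 0 log 0 = 0 convention
applies throughout.
"""

from __future__ import annotations

import math

import numpy as np

from .clustering import Clustering
from .synthetic import RANKS, TaxonomyAnnotation

__all__ = [
    "entropy",
    "mutual_information",
    "vi_distance",
    "vi_to_partial",
    "rank_clustering",
]


def _log(base: float | None):
    if base is None:
        return np.log
    lb = math.log(base)
    return lambda x: np.log(x) / lb


def contingency(C: Clustering, D: Clustering) -> np.ndarray:
    """Joint counts between the clusters of C and of D (same universe)."""
    if C.universe != D.universe:
        raise ValueError("clusterings are over different id universes")
    member_d = D.membership()
    table = np.zeros((C.n_clusters, D.n_clusters), dtype=float)
    for i, c in enumerate(C.clusters):
        for sid in c:
            table[i, member_d[sid]] += 1
    return table


def entropy(C: Clustering, base: float | None = None) -> float:
    """Entropy of the cluster-size distribution; 0 iff a single cluster."""
    sizes = C.sizes()
    p = sizes / sizes.sum()
    log = _log(base)
    return float(-(p * log(p)).sum())


def mutual_information(C: Clustering, D: Clustering, base: float | None = None) -> float:
    """Mutual information between two partitions of the same universe."""
    table = contingency(C, D)
    m = table.sum()
    pij = table / m
    pi = pij.sum(axis=1, keepdims=True)
    qj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    log = _log(base)
    terms = np.zeros_like(pij)
    terms[mask] = pij[mask] * log(pij[mask] / (pi @ qj)[mask])
    return float(max(terms.sum(), 0.0))


def vi_distance(C: Clustering, D: Clustering, base: float | None = None) -> float:
    """Variation of Information between two partitions of the same universe.

    Values below 1e-12 are snapped to exactly 0: the smallest nonzero VI of a
    partition pair is far larger on any realistic universe, so residue at
    that magnitude is floating-point cancellation from H(C)+H(D)-2I.
    """
    v = entropy(C, base) + entropy(D, base) - 2.0 * mutual_information(C, D, base)
    return 0.0 if v < 1e-12 else v


def vi_to_partial(
    C: Clustering, labels: dict[str, object], base: float | None = None
) -> float:
    """VI between C (restricted to the labeled ids) and the label partition.

    The labeled ids must be a subset of C's universe; unlabeled ids are
    dropped, following the definition of a partial clustering of the labeled
    sequences.
    """
    if not labels:
        raise ValueError("no labeled ids")
    if not set(labels) <= C.universe:
        raise ValueError("labels refer to ids outside the clustering")
    restricted = C.restrict(labels)
    D = Clustering.from_labels(labels)
    return vi_distance(restricted, D, base)


def rank_clustering(taxonomy: TaxonomyAnnotation, rank: str) -> Clustering:
    """Partition of the ids induced by their annotation at one rank.

    The species-rank partition is the reference ("truth") clustering for
    scoring OTU constructions.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    return Clustering.from_labels(taxonomy.labels(rank))


def vi_report_row(name_c: str, name_d: str, C: Clustering, D: Clustering,
                  base: float | None = None) -> dict:
    """One row of a VI report table: names, entropies, I, and VI."""
    return {
        "clustering_a": name_c,
        "clustering_b": name_d,
        "H_a": entropy(C, base),
        "H_b": entropy(D, base),
        "I": mutual_information(C, D, base),
        "VI": vi_distance(C, D, base),
    }
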