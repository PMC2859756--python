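"""Experiment orchestration: methodology sweeps, ANOVA, masking, VI-cut trials.

The central experiment is a factorial sweep over OTU methodologies -
alignment variant x distance correction x linkage x distance threshold -
scoring every resulting OTU set against the annotated species partition with
the Variation of Information (VI), then asking which factor drives the
variation (sequential multi-way ANOVA over the best methodologies), how
masking alignment columns changes the outcome, and whether semi-supervised
VI-cut beats every fixed threshold.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Clustering, agglomerate, cut_at_threshold
from .distances import distance_matrix
from .diversity import abundances, ace, chao1, shannon
from .synthetic import (
    AlignedSequenceSet,
    TaxonomyAnnotation,
    mask_columns,
    subsample_community,
)
from .vi import rank_clustering, vi_distance
from .vicut import vicut_constrained

FACTOR_ORDER = ("threshold", "msa", "clustering", "correction")

_RESULT_COLUMNS = [
    "msa",
    "correction",
    "clustering",
    "threshold",
    "n_OTUs",
    "vi_to_truth",
    "chao1",
    "ace",
    "shannon",
]


def run_sweep(
    alignment_variants: Mapping[str, AlignedSequenceSet],
    corrections: Sequence[str],
    linkages: Sequence[str],
    thresholds: Sequence[float],
    truth: Clustering,
    keep_clusterings: bool = True,
) -> tuple[pd.DataFrame, dict[tuple, Clustering]]:
    """Score every methodology grid cell against the truth partition.

    Returns one row per (variant, correction, linkage, threshold) plus, when
    requested, the clustering of every cell keyed by that tuple.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows: list[dict] = []
    kept: dict[tuple, Clustering] = {}
    for vname, seqs in alignment_variants.items():
        if set(seqs.ids) != set(truth.universe):
            raise ValueError(
                f"alignment variant {vname!r} and truth cover different ids"
            )
        for corr in corrections:
            dm = distance_matrix(seqs, corr)
            for linkage in linkages:
                tree = agglomerate(dm, linkage)
                for D in thresholds:
                    clustering = cut_at_threshold(tree, D)
                    a = abundances(clustering)
                    rows.append(
                        {
                            "msa": vname,
                            "correction": corr,
                            "clustering": linkage,
                            "threshold": float(D),
                            "n_OTUs": clustering.n_clusters,
                            "vi_to_truth": vi_distance(clustering, truth),
                            "chao1": chao1(a),
                            "ace": ace(a),
                            "shannon": shannon(a),
                        }
                    )
                    if keep_clusterings:
                        kept[(vname, corr, linkage, float(D))] = clustering
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS), kept


def distinct_clusterings(clusterings: Mapping[tuple, Clustering] | Sequence[Clustering]) -> int:
    """Number of distinct partitions (membership equality, labels ignored)."""
    values = (
        clusterings.values() if isinstance(clusterings, Mapping) else clusterings
    )
    return len({c.canonical() for c in values})


def top_k_by_vi(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k rows with lowest VI, ties broken by the factor columns."""
    if k > len(results):
        raise ValueError(f"k={k} exceeds {len(results)} rows")
    ordered = results.sort_values(
        ["vi_to_truth", "msa", "correction", "clustering", "threshold"],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def anova_factors(results: pd.DataFrame, top_k: int = 200) -> pd.DataFrame:
    """Sequential (Type I) multi-way ANOVA of VI over the four factors.

    Fits the best `top_k` methodologies with categorical main effects in the
    fixed order threshold, MSA, clustering, correction, and returns a table
    with sum-of-squares, df, mean squares, F against the residual, and p.  A
    factor constant within the selection is reported with 0 df and flagged
    in the `note` column.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = top_k_by_vi(results, top_k).copy()
    display = {
        "threshold": "Distance threshold",
        "msa": "MSA",
        "clustering": "Clustering",
        "correction": "Distance correction",
    }
    active = [f for f in FACTOR_ORDER if data[f].nunique() > 1]
    constant = [f for f in FACTOR_ORDER if f not in active]
    if not active:
        raise ValueError("all four factors are constant in the selection")
    formula = "vi_to_truth ~ " + " + ".join(f"C({f})" for f in active)
    fit = ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=1)

    rows = []
    for f in FACTOR_ORDER:
        if f in active:
            r = anova.loc[f"C({f})"]
            rows.append(
                {
                    "parameter": display[f],
                    "sum_sq": float(r["sum_sq"]),
                    "df": int(r["df"]),
                    "mean_sq": float(r["sum_sq"] / r["df"]),
                    "F": float(r["F"]),
                    "p": float(r["PR(>F)"]),
                    "note": "",
                }
            )
        else:
            rows.append(
                {
                    "parameter": display[f],
                    "sum_sq": 0.0,
                    "df": 0,
                    "mean_sq": np.nan,
                    "F": np.nan,
                    "p": np.nan,
                    "note": "constant within selection",
                }
            )
    resid = anova.loc["Residual"]
    total_ss = float(anova["sum_sq"].sum())
    total_df = int(anova["df"].sum())
    rows.append(
        {
            "parameter": "Error",
            "sum_sq": float(resid["sum_sq"]),
            "df": int(resid["df"]),
            "mean_sq": float(resid["sum_sq"] / resid["df"]),
            "F": np.nan,
            "p": np.nan,
            "note": "",
        }
    )
    rows.append(
        {
            "parameter": "Total",
            "sum_sq": total_ss,
            "df": total_df,
            "mean_sq": total_ss / total_df,
            "F": np.nan,
            "p": np.nan,
            "note": "",
        }
    )
    return pd.DataFrame(rows).set_index("parameter")


def format_p(p: float) -> str:
    """Render a p-value to 4 decimals, small values as '< 0.0001'."""
    if np.isnan(p):
        return ""
    return "< 0.0001" if p < 0.0001 else f"{p:.4f}"


def mask_comparison(
    alignment: AlignedSequenceSet,
    mask: np.ndarray,
    correction: str,
    linkage: str,
    thresholds: Sequence[float],
    truth: Clustering,
) -> pd.DataFrame:
    """Paired VI-to-truth with and without a column mask, per threshold."""
    masked = mask_columns(alignment, mask)
    out = []
    for name, seqs in (("unmasked", alignment), ("masked", masked)):
        dm = distance_matrix(seqs, correction)
        tree = agglomerate(dm, linkage)
        out.append(
            {float(D): vi_distance(cut_at_threshold(tree, D), truth) for D in thresholds}
        )
    unmasked, masked_vi = out
    return pd.DataFrame(
        {
            "threshold": list(unmasked),
            "vi_unmasked": [unmasked[D] for D in unmasked],
            "vi_masked": [masked_vi[D] for D in unmasked],
        }
    )


def _sample_labels(
    taxonomy: TaxonomyAnnotation,
    fraction: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    ids = list(taxonomy.ids)
    n_lab = int(round(fraction * len(ids)))
    if n_lab == 0:
        raise ValueError("label fraction selects zero sequences")
    chosen = rng.choice(len(ids), size=n_lab, replace=False)
    species = taxonomy.labels("species")
    return {ids[i]: species[ids[i]] for i in chosen}


def vicut_trials(
    alignment: AlignedSequenceSet,
    taxonomy: TaxonomyAnnotation,
    label_fraction: float = 0.10,
    n_trials: int = 20,
    correction: str = "JC",
    linkage: str = "furthest",
    seed: int = 0,
    diameter_threshold: float = 0.07,
) -> pd.DataFrame:
    """Repeated VI-cut runs under random partial labelings.

    Each trial labels a random `label_fraction` of the sequences with their
    true species, runs diameter-constrained VI-cut on the fixed tree, and
    scores the output against the *full* species partition.
    """
    if not (0.0 < label_fraction <= 1.0):
        raise ValueError("label fraction must be in (0, 1]")
    dm = distance_matrix(alignment, correction)
    tree = agglomerate(dm, linkage)
    truth = rank_clustering(taxonomy, "species")
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        labels = _sample_labels(taxonomy, label_fraction, rng)
        result = vicut_constrained(tree, labels, dm, diameter_threshold)
        rows.append(
            {
                "trial": trial,
                "n_labeled": len(labels),
                "n_OTUs": result.clustering.n_clusters,
                "vi_to_truth": vi_distance(result.clustering, truth),
            }
        )
    return pd.DataFrame(rows)


def subsample_experiment(
    alignment_variants: Mapping[str, AlignedSequenceSet],
    taxonomy: TaxonomyAnnotation,
    methodologies: Sequence[tuple[str, str, str, float | str]],
    n: int = 500,
    n_samples: int = 10,
    seed: int = 0,
    label_fraction: float = 0.10,
    diameter_threshold: float = 0.07,
) -> pd.DataFrame:
    """Mean VI per methodology over repeated random subsamples.

    `methodologies` holds (msa, correction, linkage, threshold) tuples where
    threshold may be the string "adaptive" for diameter-constrained VI-cut
    (labels drawn afresh per sample).  Each sample of size `n` is shared
    across methodologies; output rows mirror (MSA, Clustering, Distance,
    mean VI).
    """
    some_variant = next(iter(alignment_variants.values()))
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    vi_acc: dict[int, list[float]] = {i: [] for i in range(len(methodologies))}

    for s_seed in sample_seeds:
        _, sub_tax = subsample_community(some_variant, taxonomy, n, int(s_seed))
        ids = set(sub_tax.ids)
        truth = rank_clustering(sub_tax, "species")
        label_rng = np.random.default_rng(int(s_seed) + 1)
        labels = _sample_labels(sub_tax, label_fraction, label_rng)
        cache: dict[tuple, tuple] = {}
        for mi, (msa, corr, linkage, D) in enumerate(methodologies):
            key = (msa, corr, linkage)
            if key not in cache:
                seqs = alignment_variants[msa]
                keep = [i for i, sid in enumerate(seqs.ids) if sid in ids]
                sub = AlignedSequenceSet(
                    tuple(seqs.ids[i] for i in keep),
                    tuple(seqs.rows[i] for i in keep),
                )
                dm = distance_matrix(sub, corr)
                cache[key] = (dm, agglomerate(dm, linkage))
            dm, tree = cache[key]
            if D == "adaptive":
                clustering = vicut_constrained(
                    tree, labels, dm, diameter_threshold
                ).clustering
            else:
                clustering = cut_at_threshold(tree, float(D))
            vi_acc[mi].append(vi_distance(clustering, truth))

    rows = [
        {
            "msa": msa,
            "clustering": linkage,
            "threshold": D if D == "adaptive" else float(D),
            "correction": corr,
            "mean_vi": float(np.mean(vi_acc[mi])),
        }
        for mi, (msa, corr, linkage, D) in enumerate(methodologies)
    ]
    return pd.DataFrame(rows).sort_values("mean_vi").reset_index(drop=True)
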