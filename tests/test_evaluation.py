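"""Sweep orchestration, distinct-clustering count, sequential ANOVA, masking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from otubench import (
    Clustering,
    CommunityConfig,
    agglomerate,
    anova_factors,
    cut_at_threshold,
    distance_matrix,
    distinct_clusterings,
    generate_community,
    mask_comparison,
    rank_clustering,
    run_sweep,
    subsample_experiment,
    top_k_by_vi,
    vi_distance,
    vicut_trials,
)
from otubench.synthetic import AlignedSequenceSet


@pytest.fixture(scope="module")
def mini_sweep():
    cfg = CommunityConfig(
        n_species=6,
        total_sequences=48,
        alignment_length=500,
        rank_tree_shape=(2, 2, 3, 4, 5),
        n_confusable_pairs=1,
        seed=17,
    )
    seqs, tax = generate_community(cfg)
    truth = rank_clustering(tax, "species")
    from otubench import perturb_alignment_variant

    variants = {
        "base": seqs,
        "jitter": perturb_alignment_variant(seqs, 0.02, 1),
    }
    thresholds = [0.0, 0.02, 0.05, 0.10, 0.20]
    results, kept = run_sweep(
        variants, ["JC", "K2P"], ["nearest", "furthest"], thresholds, truth
    )
    return variants, tax, truth, thresholds, results, kept


class TestRunSweep:
    def test_row_count_is_grid_product(self, mini_sweep):
        variants, _, _, thresholds, results, _ = mini_sweep
        assert len(results) == len(variants) * 2 * 2 * len(thresholds)

    def test_single_cell_matches_direct_vi(self, mini_sweep):
        variants, _, truth, _, _, _ = mini_sweep
        seqs = variants["base"]
        results, _ = run_sweep({"base": seqs}, ["JC"], ["furthest"], [0.05], truth)
        assert len(results) == 1
        dm = distance_matrix(seqs, "JC")
        direct = vi_distance(
            cut_at_threshold(agglomerate(dm, "furthest"), 0.05), truth
        )
        assert results["vi_to_truth"].iloc[0] == pytest.approx(direct, abs=1e-12)

    def test_clean_community_reaches_vi_zero(self):
        cfg = CommunityConfig(
            n_species=5,
            total_sequences=40,
            alignment_length=600,
            species_diameter_range=(0.005, 0.03),
            between_species_divergence=0.2,
            rank_tree_shape=(1, 2, 3, 4, 5),
            n_confusable_pairs=0,
            seed=29,
        )
        seqs, tax = generate_community(cfg)
        truth = rank_clustering(tax, "species")
        results, _ = run_sweep(
            {"base": seqs}, ["JC"], ["furthest"],
            [0.01, 0.03, 0.05, 0.08], truth,
        )
        best = results.loc[results["vi_to_truth"].idxmin()]
        assert best["vi_to_truth"] == pytest.approx(0.0, abs=1e-12)
        assert best["n_OTUs"] == 5

    def test_id_mismatch_rejected(self, mini_sweep):
        variants, _, truth, _, _, _ = mini_sweep
        seqs = variants["base"]
        short = AlignedSequenceSet(seqs.ids[:-1], seqs.rows[:-1])
        with pytest.raises(ValueError):
            run_sweep({"x": short}, ["JC"], ["furthest"], [0.05], truth)


class TestDistinct:
    def test_matches_pairwise_oracle(self, mini_sweep):
        *_, kept = mini_sweep
        clusterings = list(kept.values())
        count = distinct_clusterings(clusterings)
        # O(k^2) brute force over membership equality
        distinct = []
        for c in clusterings:
            if not any(c.canonical() == d.canonical() for d in distinct):
                distinct.append(c)
        assert count == len(distinct)

    def test_duplicates_counted_once(self):
        c = Clustering.from_sets([{"a"}, {"b"}])
        d = Clustering.from_sets([{"b"}, {"a"}])
        assert distinct_clusterings([c, d]) == 1

    def test_thresholds_above_root_height_collapse(self, mini_sweep):
        variants, _, truth, _, _, _ = mini_sweep
        dm = distance_matrix(variants["base"], "JC")
        root_h = float(agglomerate(dm, "furthest").heights.max())
        results, kept = run_sweep(
            {"base": variants["base"]}, ["JC"], ["furthest"],
            [root_h + 0.01, root_h + 0.02], truth,
        )
        assert (results["n_OTUs"] == 1).all()
        assert distinct_clusterings(kept) == 1


class TestTopK:
    def test_sorted_prefix_property(self, mini_sweep):
        *_, results, _ = mini_sweep
        top = top_k_by_vi(results, 5)
        assert (top["vi_to_truth"].diff().dropna() >= 0).all()
        assert top["vi_to_truth"].max() <= results["vi_to_truth"].min() + (
            np.sort(results["vi_to_truth"].to_numpy())[4]
            - results["vi_to_truth"].min()
        ) + 1e-12

    def test_k_equal_rows_is_full_sort(self, mini_sweep):
        *_, results, _ = mini_sweep
        top = top_k_by_vi(results, len(results))
        assert np.allclose(
            np.sort(results["vi_to_truth"].to_numpy()),
            top["vi_to_truth"].to_numpy(),
        )


def sequential_ss_oracle(data, factors, response):
    """Brute-force Type I SS: RSS drop when adding each factor in order."""

    def design(cols):
        X = [np.ones(len(data))]
        for f in cols:
            levels = sorted(data[f].unique())
            for lev in levels[1:]:
                X.append((data[f] == lev).to_numpy(float))
        return np.column_stack(X)

    y = data[response].to_numpy(float)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    out = {}
    prev = rss(design([]))
    for i, f in enumerate(factors):
        cur = rss(design(factors[: i + 1]))
        out[f] = prev - cur
        prev = cur
    out["error"] = prev
    return out


class TestAnova:
    def test_balanced_toy_matches_projection_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for t, m in itertools.product([0.01, 0.03, 0.05], ["x", "y"]):
            for _ in range(4):
                rows.append(
                    {
                        "threshold": t,
                        "msa": m,
                        "clustering": "furthest",
                        "correction": "JC",
                        "vi_to_truth": 0.1
                        + 2.0 * t
                        + (0.05 if m == "y" else 0.0)
                        + rng.normal(0, 0.01),
                    }
                )
        data = pd.DataFrame(rows)
        table = anova_factors(data, top_k=len(data))
        oracle = sequential_ss_oracle(
            data, ["threshold", "msa"], "vi_to_truth"
        )
        assert table.loc["Distance threshold", "sum_sq"] == pytest.approx(
            oracle["threshold"], abs=1e-9
        )
        assert table.loc["MSA", "sum_sq"] == pytest.approx(oracle["msa"], abs=1e-9)
        assert table.loc["Error", "sum_sq"] == pytest.approx(
            oracle["error"], abs=1e-9
        )
        # constant factors flagged with 0 df
        assert table.loc["Clustering", "df"] == 0
        assert "constant" in table.loc["Clustering", "note"]

    def test_f_is_ms_ratio_and_df_add_up(self, mini_sweep):
        *_, results, _ = mini_sweep
        table = anova_factors(results, top_k=len(results))
        err_ms = table.loc["Error", "mean_sq"]
        for factor in ("Distance threshold", "MSA", "Clustering"):
            if table.loc[factor, "df"] > 0:
                assert table.loc[factor, "F"] == pytest.approx(
                    table.loc[factor, "mean_sq"] / err_ms, abs=1e-9
                )
        factor_rows = table.drop(index=["Total"])
        assert factor_rows["df"].sum() == table.loc["Total", "df"] + 0
        assert factor_rows["sum_sq"].sum() == pytest.approx(
            table.loc["Total", "sum_sq"], abs=1e-9
        )

    def test_constant_response_gives_zero_ss(self):
        rows = [
            {
                "threshold": t,
                "msa": m,
                "clustering": c,
                "correction": "JC",
                "vi_to_truth": 0.5,
            }
            for t, m, c in itertools.product(
                [0.01, 0.02], ["x", "y"], ["nearest", "furthest"]
            )
        ]
        table = anova_factors(pd.DataFrame(rows), top_k=len(rows))
        for factor in ("Distance threshold", "MSA", "Clustering"):
            assert table.loc[factor, "sum_sq"] == pytest.approx(0.0, abs=1e-12)


class TestMaskComparison:
    def test_all_true_mask_is_no_op(self, mini_sweep):
        variants, _, truth, thresholds, _, _ = mini_sweep
        seqs = variants["base"]
        df = mask_comparison(
            seqs, np.ones(seqs.n_columns, bool), "JC", "furthest", thresholds, truth
        )
        assert np.allclose(df["vi_masked"], df["vi_unmasked"])

    def test_invariant_column_removal_rescales_thresholds(self):
        # alignment whose first 60 columns are invariant: removing them scales
        # every p-distance by 2, so cutting at 2D reproduces the cut at D
        rng = np.random.default_rng(44)
        base = rng.integers(0, 4, size=120)
        rows = []
        for i in range(10):
            row = base.copy()
            hot = rng.choice(np.arange(60, 120), size=3, replace=False)
            row[hot] = (row[hot] + rng.integers(1, 4, size=3)) % 4
            rows.append("".join("AGCT"[b] for b in row))
        seqs = AlignedSequenceSet(tuple(f"s{i}" for i in range(10)), tuple(rows))
        mask = np.arange(120) >= 60
        from otubench import mask_columns

        dm_full = distance_matrix(seqs, "NONE")
        dm_masked = distance_matrix(mask_columns(seqs, mask), "NONE")
        t_full = agglomerate(dm_full, "furthest")
        t_masked = agglomerate(dm_masked, "furthest")
        for D in (0.01, 0.02, 0.04):
            a = cut_at_threshold(t_full, D)
            b = cut_at_threshold(t_masked, 2 * D)
            assert a.canonical() == b.canonical()

    def test_mask_hiding_species_signal_hurts(self):
        # two species separated only by the first 10 columns; masking them
        # away makes the best achievable VI strictly worse
        rng = np.random.default_rng(55)
        core = rng.integers(0, 4, size=110)
        rows, ids, labels = [], [], {}
        for sp, block in (("A", 0), ("B", 2)):
            for i in range(6):
                row = np.concatenate([np.full(10, block), core.copy()])
                hot = rng.choice(np.arange(10, 120), size=2, replace=False)
                row[hot] = (row[hot] + rng.integers(1, 4, size=2)) % 4
                sid = f"{sp}{i}"
                ids.append(sid)
                labels[sid] = sp
                rows.append("".join("AGCT"[b] for b in row))
        seqs = AlignedSequenceSet(tuple(ids), tuple(rows))
        truth = Clustering.from_labels(labels)
        mask = np.arange(120) >= 10
        grid = [0.01, 0.03, 0.05, 0.08, 0.12]
        df = mask_comparison(seqs, mask, "JC", "furthest", grid, truth)
        assert df["vi_masked"].min() > df["vi_unmasked"].min()


class TestVicutTrials:
    def test_full_labels_clean_community_gives_zero(self):
        cfg = CommunityConfig(
            n_species=5,
            total_sequences=30,
            alignment_length=500,
            species_diameter_range=(0.005, 0.02),
            between_species_divergence=0.2,
            rank_tree_shape=(1, 2, 3, 4, 5),
            n_confusable_pairs=0,
            seed=61,
        )
        seqs, tax = generate_community(cfg)
        trials = vicut_trials(
            seqs, tax, label_fraction=1.0, n_trials=3, seed=0
        )
        assert np.allclose(trials["vi_to_truth"], 0.0, atol=1e-12)

    def test_reproducible_given_seed(self, small_community):
        _, seqs, tax = small_community
        a = vicut_trials(seqs, tax, n_trials=4, seed=9)
        b = vicut_trials(seqs, tax, n_trials=4, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 4

    def test_zero_label_fraction_rejected(self, small_community):
        _, seqs, tax = small_community
        with pytest.raises(ValueError):
            vicut_trials(seqs, tax, label_fraction=0.0)


class TestSubsampleExperiment:
    def test_single_full_sample_equals_direct_vi(self, mini_sweep):
        variants, tax, truth, _, _, _ = mini_sweep
        seqs = variants["base"]
        methodologies = [("base", "JC", "furthest", 0.03), ("base", "JC", "furthest", 0.10)]
        df = subsample_experiment(
            {"base": seqs}, tax, methodologies, n=len(seqs), n_samples=1, seed=0
        )
        assert len(df) == 2
        dm = distance_matrix(seqs, "JC")
        tree = agglomerate(dm, "furthest")
        for _, row in df.iterrows():
            direct = vi_distance(cut_at_threshold(tree, row["threshold"]), truth)
            assert row["mean_vi"] == pytest.approx(direct, abs=1e-12)

    def test_row_count_and_adaptive_rows(self, mini_sweep):
        variants, tax, *_ = mini_sweep
        methodologies = [
            ("base", "JC", "furthest", "adaptive"),
            ("base", "JC", "furthest", 0.03),
            ("jitter", "JC", "furthest", 0.03),
        ]
        df = subsample_experiment(
            variants, tax, methodologies, n=30, n_samples=2, seed=3
        )
        assert len(df) == 3
        assert (df["threshold"] == "adaptive").sum() == 1
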