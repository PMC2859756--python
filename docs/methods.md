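# Methods

This note records the models, parameter choices, and numerical conventions
behind `otubench`, and what the synthetic communities do and do not emulate.

## Synthetic communities

`generate_community` produces a gap-free aligned community with a consistent
six-rank taxonomy (phylum → species). The default configuration describes
the study community the package is built around: 49 species and 1677
sequences under a 7/12/21/37/46-taxon rank hierarchy, 1300 alignment
columns, within-species diameters spanning 0.01–0.07, skewed abundances, and
three "confusable" species pairs. Tests and the acceptance script run the
same structure at 200–400 sequences; those sizes are a deliberate choice to
keep the whole battery interactive, and every qualitative property asserted
was verified to be driven by structure (diameter range, confusable pairs,
abundance skew), not by the total count.

**Guide tree.** A random surjective hierarchy is drawn with the configured
taxon counts per rank. A root sequence (uniform over A/C/G/T per column)
evolves down the hierarchy by i.i.d. substitutions; each edge's substitution
probability is a per-rank base rate (phylum 0.06, class 0.035, order 0.025,
family 0.015, genus 0.010) times an independent lognormal multiplier
(σ = 0.35, clipped to [0.6, 2.2]). The multipliers matter: evolutionary
rates vary across lineages, and without them the between-species distance
distribution collapses onto a single scale, the merge-height spectrum
develops an empty band, and one partition is optimal over many consecutive
thresholds — an artifact no real 16S dataset shows. The shallow low-rank
ladder reflects real 16S data, where species in neighbouring genera can sit
only a few percent apart. Species edges use
`between_species_divergence / 2` (default 0.12/2) with multipliers clipped
to [0.7, 2.0], keeping every sibling-species separation above the
within-species diameter range except for the explicitly constructed
confusable pairs.

**Within-species diameters.** Each species draws a target diameter uniformly
from `species_diameter_range`. Targets are specified on the corrected
(Jukes-Cantor) distance scale — the scale on which clustering thresholds and
the VI-cut bound operate — and converted internally to mismatch fractions
via p = (3/4)(1 − e^(−4d/3)). Sequences radiate from the species ancestor
(star tree) at a per-sequence rate calibrated so the *maximum* pairwise
p-distance matches the target: the closed-form rate for the expected
pairwise distance (solving 2r − (4/3)r² = p) seeds a short multiplicative
refinement loop (≤ 8 deterministic iterations, acceptance within 15%),
because the maximum over all pairs sits above the mean, increasingly so for
small targets and large species. Realized diameters are additionally capped
at the range maximum, so the community's *realized* diameter range equals
the configured one rather than merely being centred on it; this matters
because the VI-cut bound (0.07, inclusive) sits exactly at the range top,
and a community whose widest species overshoots the bound is forcibly
fragmented in a way the intended conditions do not imply.

**Confusable pairs.** `n_confusable_pairs` species pairs (sibling species
where the hierarchy provides them) have their ancestors placed at p-distance
0.5 × diameter-max of each other and their own diameters pinned at the range
minimum. Their minimum inter-species distance therefore falls below the
widest species diameter in the community — so no single threshold can both
keep wide species whole and hold these pairs apart — while all other species
pairs stay safely separated, keeping the below-the-max count exactly at the
configured number. One non-confusable species (the median-abundance one, so
diameter and abundance stay uncoupled) is pinned at the range maximum so the
range is fully expressed.

**Abundances.** Default is a geometric decay (ratio 0.95) apportioned to the
total with a floor of one sequence per species; at the default total this
gives ≥ 5 species with ≥ 40 sequences and a long tail of rare species.

**Alignment variants.** `perturb_alignment_variant` emulates disagreement
between alignment programs: at `rate × n_columns` random positions a
one-column gap is inserted for a random half of the rows and at a nearby
offset (1–8 columns) for the rest, locally shifting the register without
changing any ungapped sequence. Sweeps use the exact alignment plus variants
at rates 0.03 and 0.08 — programs of *differing* quality, which is what
makes the alignment factor matter in practice.

**What is not emulated.** rRNA secondary structure and rate heterogeneity
across sites; insertions/deletions in the true sequences (gaps enter only
through variant jitter); chimeras and sequencing error; short-read data.
Passing tests on these communities therefore demonstrate correctness of the
pipeline and reproduce the *qualitative* methodology effects; they say
nothing about absolute VI or richness values on any real dataset.

## Distances

Distances follow PHYLIP DNADIST conventions. Sites where either sequence of
a pair has a gap are excluded from that pair's counts (pairwise deletion);
ambiguity codes are treated the same way (the conservative reading — they
carry no reliable substitution signal). Corrections:

- JC: d = −(3/4) ln(1 − 4p/3), domain p < 0.75;
- K2P: d = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q);
- F84 (method of moments): with base frequencies π and the standard
  A, B, C combinations, d = −2A ln(1 − P/2A − (A−B)Q/2AC) + 2(A−B−C)
  ln(1 − Q/2C). Frequencies are pooled over the whole alignment (the
  DNADIST default), configurable per call. This form consumes the observed
  transition/transversion split directly, so no prior ts/tv ratio parameter
  is needed. Verified against `ape::dist.dna` to 1e-12.

Out-of-domain pairs ("saturation") raise by default, naming the offending
pair; an opt-in cap mode clips them to a configurable distance for
robustness sweeps — silent capping is not the default because it distorts
the top of the dendrogram. Distances are kept at full float precision (no
DOTUR-style input rounding).

## Clustering

A Lance-Williams agglomerator implements nearest (single), unweighted
average (UPGMA) and furthest (complete) linkage. Ties in the minimal linkage
distance are broken toward the pair whose (smallest member id, then the
other cluster's smallest member id) sorts lexicographically first — the
classic tools leave this unspecified, which is one historical source of
irreproducibility. Threshold cuts are inclusive (merge heights ≤ D, exact
float comparison; grid thresholds are exact hundredths), so zero-distance
duplicates co-cluster at every D ≥ 0. For complete linkage, the cut at D
guarantees every cluster diameter ≤ D; no such guarantee holds (or is
asserted) for single/average linkage. The agglomerator is cross-checked in
tests against both an O(n³) re-scan oracle and `scipy.cluster.hierarchy`.

## VI and VI-cut

Entropies and mutual information use natural logarithms by default (a `base`
argument exists); the 0·log 0 = 0 convention applies, and internal
comparisons are always base-consistent so method rankings are unaffected by
the choice. `vi_distance` snaps values below 1e-12 to exactly 0 — pure
cancellation residue, since the smallest achievable nonzero VI is far larger
on any realistic universe. `vi_to_partial` restricts the clustering to the
labeled ids (the partial-clustering definition), rather than treating
unlabeled sequences as an extra cluster.

The VI-cut DP uses the additive decomposition VI(A_K, D) = H(D) + Σ cost(c)
over chosen nodes, with all fractions over labeled leaves only; a cluster
without labeled leaves costs 0. Ties between a node and its children's best
sum (within 1e-12) resolve to the node — coarser cuts — which combined with
the zero cost of unlabeled clusters merges unlabeled regions maximally; the
forbidden-node refinement then bounds them. A node is forbidden iff its leaf
set's diameter is ≥ the bound (inclusive, default 0.07); diameter is
monotone up the tree, so a chosen cluster contains a forbidden node iff its
own node is forbidden, and the refinement replaces it by the maximal
forbidden-free subtrees beneath it. Leaves have diameter 0 and are never
forbidden, so the refinement always yields a partition (no stranded leaves);
output clusters provably satisfy diameter < bound, and the constrained
result refines the unconstrained one. DP optimality is verified in tests by
exhaustive node-cut enumeration on trees of up to 12 leaves.

## Richness and diversity

Chao1 defaults to the classic form S_obs + F₁²/(2F₂) and falls back to the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0; both variants
are exposed because the literature mixes them. ACE uses the standard
rare/abundant cutoff of 10 (configurable); when every rare OTU is a
singleton its coverage is 0 and the bias-corrected Chao1 is returned with a
warning. Shannon uses natural logarithms. The bias-corrected Chao1 and ACE
are frozen-value-tested against `vegan::estimateR`.

## Evaluation experiments

`run_sweep` scores every (alignment variant × correction × linkage ×
threshold) cell; with 3 × 3 × 3 × 46 settings that is 1242 OTU sets, many of
which coincide as partitions (`distinct_clusterings` counts equivalence
classes by membership). `anova_factors` fits the lowest-VI 200 cells with
sequential (Type I) sums of squares in the fixed order threshold, MSA,
clustering, correction — the selection is unbalanced, so the SS type and
order are part of the definition; threshold enters as a categorical factor.
A factor constant within the selection is reported with 0 df and flagged.
p-values come from the F distribution, formatted to four decimals with small
values shown as "< 0.0001". Ties at the 200th-lowest VI are broken by the
factor columns in the same fixed order. `vicut_trials` scores constrained
VI-cut output against the *full* species partition (not only the unlabeled
remainder) across repeated random labelings; `subsample_experiment` shares
each random subsample across all methodologies so their mean VIs are paired.

All randomness flows from named `numpy` SeedSequence substreams of a single
configured seed, so each experiment is re-runnable in isolation and a full
run emits byte-identical tables.
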