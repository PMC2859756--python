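# otubench

Evaluation of OTU-construction methodologies for 16S rRNA diversity surveys.

Microbial diversity studies cluster 16S rRNA sequences into *operational
taxonomic units* (OTUs) by applying a distance threshold to a hierarchical
clustering of pairwise evolutionary distances. Every step of that pipeline —
the multiple alignment, the distance correction, the linkage rule, and above
all the threshold — is a free parameter, and small changes in it move the
estimated richness of a community by factors of 2–10. `otubench` provides a
controlled test bench for this problem: it simulates aligned 16S-like
communities with a known six-rank taxonomy, sweeps the full methodology grid,
scores every OTU set against the annotated species partition with the
Variation of Information metric, and runs the semi-supervised *VI-cut*
alternative that picks local thresholds from a partially labeled tree.

It is aimed at microbial ecologists and method developers who want to
quantify how analysis choices — not biology — drive OTU counts, Chao1/ACE
richness estimates, and Shannon diversity.

## The quantities at the core

For a partition *C* of *m* sequences with cluster sizes *m<sub>i</sub>*, write
*p<sub>i</sub> = m<sub>i</sub>/m*. With a second partition *D* and joint cell
fractions *p<sub>ij</sub>*:

- entropy  H(C) = −Σ<sub>i</sub> p<sub>i</sub> log p<sub>i</sub>
- mutual information  I(C,D) = Σ<sub>ij</sub> p<sub>ij</sub> log [p<sub>ij</sub> / (p<sub>i</sub> q<sub>j</sub>)]
- **Variation of Information**  VI(C,D) = H(C) + H(D) − 2 I(C,D)

VI is a true metric on partitions (zero iff identical, symmetric, triangle
inequality), which makes it a principled score for "how far is this OTU set
from the annotated species partition".

Pairwise distances follow PHYLIP DNADIST conventions (gap sites excluded
pair-by-pair) with the Jukes-Cantor, Kimura 2-parameter, and F84 corrections.
Clustering is agglomerative with nearest/average/furthest-neighbor linkage;
OTUs at threshold *D* are the maximal subtrees whose merge heights are ≤ *D*.
Richness and diversity come from the OTU abundance vector: Chao1
(S<sub>obs</sub> + F₁²/2F₂), ACE (rare-OTU coverage estimator, cutoff 10),
and Shannon H = −Σ (n<sub>i</sub>/N) ln(n<sub>i</sub>/N).

**VI-cut** selects, by dynamic programming, the antichain of dendrogram nodes
whose induced clustering minimizes VI to a *partial* labeling (taxonomy known
for a small fraction of sequences). Nodes whose subtree diameter is ≥ 0.07
are *forbidden*: clusters containing one are subdivided into the maximal
forbidden-free subtrees, bounding every OTU below 7% divergence while letting
the effective threshold vary across the tree.

## Worked example

```python
import numpy as np
from otubench import (CommunityConfig, generate_community, distance_matrix,
                      agglomerate, cut_at_threshold, rank_clustering,
                      vi_distance, vicut_constrained, abundances,
                      chao1, ace, shannon)

cfg = CommunityConfig(total_sequences=400, seed=1)   # 49 species, known taxonomy
seqs, tax = generate_community(cfg)
truth = rank_clustering(tax, "species")
dm = distance_matrix(seqs, "JC")
tree = agglomerate(dm, "furthest")

for D in (0.01, 0.03, 0.05, 0.06, 0.07, 0.10):
    c = cut_at_threshold(tree, D)
    a = abundances(c)
    print(D, c.n_clusters, round(chao1(a), 1), round(shannon(a), 3),
          round(vi_distance(c, truth), 4))
```

prints (columns: D, OTUs, Chao1, ACE, Shannon, VI to the species truth):

```
    D  OTUs   Chao1     ACE  Shannon      VI
 0.01   348  7320.2 10110.2    5.679  2.0229
 0.03   219  1791.5  1725.7    4.820  1.1633
 0.05   102   310.3   205.6    4.070  0.4539
 0.06    60    81.1    68.5    3.748  0.1503
 0.07    46    46.0    46.0    3.627  0.0295
 0.10    46    46.0    46.0    3.627  0.0295
truth    49    49.0    49.0    3.657
```

The community contains 49 species, yet the conventional "species-level"
thresholds 0.01–0.03 report hundreds of OTUs and a Chao1 in the thousands —
the richness inflation that motivates the package. The best fixed threshold
here is far above 0.03 and still cannot reach VI 0: a few species pairs are
separated by less than other species' internal diameters, so no single
threshold is right everywhere. Supplying true labels for a random 10% of
sequences to diameter-constrained VI-cut:

```python
rng = np.random.default_rng(1)
species = tax.labels("species")
chosen = rng.choice(len(seqs), size=40, replace=False)
labels = {seqs.ids[i]: species[seqs.ids[i]] for i in chosen}
result = vicut_constrained(tree, labels, dm, diameter_threshold=0.07)
print(result.clustering.n_clusters,
      round(vi_distance(result.clustering, truth), 4))
# -> 46 OTUs, VI 0.0295
```

matches the best fixed threshold without having to know it, and across
repeated labelings its mean VI beats every fixed threshold on the grid (see
`otubench.evaluation.vicut_trials`).

A thin CLI mirrors the stages: `otubench simulate | dist | cluster | vi |
vicut | diversity | sweep | evaluate` (see `otubench --help`).

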