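import numpy as np
import pytest

from otubench import (
    CommunityConfig,
    DistanceMatrix,
    generate_community,
    rank_clustering,
)
from otubench.clustering import Clustering


@pytest.fixture(scope="session")
def small_community():
    """A 10-species, 80-sequence community with one confusable pair."""
    cfg = CommunityConfig(
        n_species=10,
        total_sequences=80,
        alignment_length=600,
        rank_tree_shape=(2, 3, 4, 6, 8),
        n_confusable_pairs=1,
        seed=5,
    )
    seqs, tax = generate_community(cfg)
    return cfg, seqs, tax


@pytest.fixture(scope="session")
def study_community():
    """The default community structure at a 200-sequence problem size."""
    cfg = CommunityConfig(total_sequences=200, seed=1)
    seqs, tax = generate_community(cfg)
    return cfg, seqs, tax


@pytest.fixture(scope="session")
def species_truth(study_community):
    _, _, tax = study_community
    return rank_clustering(tax, "species")


@pytest.fixture
def toy_matrix():
    """3 ids: d(a,b)=0.01, d(a,c)=d(b,c)=0.10."""
    v = np.array([[0.0, 0.01, 0.10], [0.01, 0.0, 0.10], [0.10, 0.10, 0.0]])
    return DistanceMatrix(("a", "b", "c"), v)


@pytest.fixture
def paired_matrix():
    """4 ids: d(a,b)=d(c,d)=0.02, all cross distances 0.2."""
    v = np.full((4, 4), 0.2)
    np.fill_diagonal(v, 0.0)
    v[0, 1] = v[1, 0] = 0.02
    v[2, 3] = v[3, 2] = 0.02
    return DistanceMatrix(("a", "b", "c", "d"), v)


def random_partition(ids, rng, max_clusters=None):
    """Uniform-ish random partition of `ids` for metric tests."""
    ids = list(ids)
    k = int(rng.integers(1, (max_clusters or len(ids)) + 1))
    assignment = rng.integers(0, k, size=len(ids))
    groups = {}
    for sid, g in zip(ids, assignment):
        groups.setdefault(int(g), set()).add(sid)
    return Clustering.from_sets(groups.values())


def random_distance_matrix(n, rng, scale=1.0):
    v = rng.random((n, n)) * scale
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    ids = tuple(f"x{i:03d}" for i in range(n))
    return DistanceMatrix(ids, v)
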