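"""Simulation of aligned 16S-like communities with known six-rank taxonomy.

The generator emulates a curated environmental survey: a fixed number of
species arranged under a consistent phylum → class → order → family → genus →
species hierarchy, skewed abundances, and controlled within-species sequence
heterogeneity.  Within-species "diameters" (the maximum pairwise uncorrected
distance inside a species) are drawn from a configurable range, reproducing
the observation that no single clustering threshold suits every species.  A
configurable number of "confusable" species pairs are placed closer together
than the widest species is internally diverse, so that threshold-based OTU
construction cannot be perfect.

Sequences are evolved by i.i.d. nucleotide substitutions down the rank
hierarchy (a star tree within each species).  The core alignment is gap-free;
gaps enter only through :func:`perturb_alignment_variant`, which emulates the
disagreement between multiple-alignment programs by locally jittering gap
placement without touching the ungapped sequence content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._seq import decode_row, encode_rows, p_distance_matrix

RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: per-edge substitution probability for each internal rank level (the species
#: edge rate is derived from ``between_species_divergence``).  The ladder is
#: shallow at low ranks, as in real 16S data where species of neighbouring
#: genera can sit only a few percent apart, and steepens toward the phylum
#: level; per-edge lognormal rate multipliers spread the realized
#: separations into a continuum.
_RANK_EDGE_RATES = {
    "phylum": 0.06,
    "class": 0.035,
    "order": 0.025,
    "family": 0.015,
    "genus": 0.010,
}

_RANK_PREFIX = dict(zip(RANKS, ("P", "C", "O", "F", "G", "S")))


class ConfigurationError(ValueError):
    """Raised when a community configuration is internally infeasible."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An ordered set of equal-length gapped sequences (the MSA under study)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows are not all the same length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def to_codes(self) -> np.ndarray:
        return encode_rows(list(self.rows))

    def ungapped(self) -> dict[str, str]:
        return {i: r.replace("-", "") for i, r in zip(self.ids, self.rows)}


@dataclass(frozen=True)
class TaxonomyAnnotation:
    """Per-sequence labels at the six ranks phylum → species."""

    table: pd.DataFrame  # index = sequence id, columns = RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.table.columns]
        if missing:
            raise ValueError(f"taxonomy table lacks ranks: {missing}")
        if self.table[list(RANKS)].isna().any().any():
            raise ValueError("taxonomy table has missing labels")
        # hierarchy consistency: equal label at a finer rank implies equal
        # label at every coarser rank
        for fine, coarse in zip(RANKS[::-1], RANKS[-2::-1]):
            per = self.table.groupby(fine)[coarse].nunique()
            bad = per[per > 1]
            if len(bad):
                raise ValueError(
                    f"inconsistent hierarchy: {fine} {bad.index[0]!r} maps to "
                    f"{bad.iloc[0]} distinct {coarse} labels"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def labels(self, rank: str) -> dict[str, str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.table[rank].to_dict()


@dataclass
class CommunityConfig:
    """Parameters of a simulated community.

    Defaults describe the study community: 49 species over a
    7/12/21/37/46-taxon rank hierarchy, 1677 sequences with a geometric
    abundance skew, 1300 alignment columns, within-species diameters drawn
    uniformly from [0.01, 0.07], and three confusable species pairs.

    ``species_diameter_range`` is specified on the *corrected* evolutionary
    distance scale (Jukes-Cantor), the scale on which clustering thresholds
    and the VI-cut diameter bound operate; the generator converts targets to
    mismatch fractions internally.
    """

    n_species: int = 49
    total_sequences: int = 1677
    alignment_length: int = 1300
    species_diameter_range: tuple[float, float] = (0.01, 0.07)
    between_species_divergence: float = 0.12
    rank_tree_shape: tuple[int, int, int, int, int] = (7, 12, 21, 37, 46)
    n_confusable_pairs: int = 3
    abundance_skew: float = 0.95
    abundance_counts: tuple[int, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.species_diameter_range
        if not (0.0 <= lo <= hi):
            raise ConfigurationError("diameter range must satisfy 0 <= lo <= hi")
        if hi >= self.between_species_divergence:
            raise ConfigurationError(
                "species diameters must stay below the between-species divergence"
            )
        if self.n_species < 1 or self.total_sequences < self.n_species:
            raise ConfigurationError("need at least one sequence per species")
        shape = (*self.rank_tree_shape, self.n_species)
        if any(a > b for a, b in zip(shape, shape[1:])) or shape[0] < 1:
            raise ConfigurationError(
                "rank_tree_shape must be non-decreasing and end at n_species"
            )
        if 2 * self.n_confusable_pairs > self.n_species:
            raise ConfigurationError("too many confusable pairs for n_species")
        if self.abundance_counts is not None:
            if len(self.abundance_counts) != self.n_species:
                raise ConfigurationError("abundance_counts length != n_species")
            if any(c < 1 for c in self.abundance_counts):
                raise ConfigurationError("every species needs >= 1 sequence")
            if sum(self.abundance_counts) != self.total_sequences:
                raise ConfigurationError("abundance_counts must sum to total")


# ---------------------------------------------------------------------------
# internals


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability `rate` (to one of
    the three other bases, uniformly)."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 4, size=k)) % 4
    return out


def _rate_for_diameter(d: float) -> float:
    # E[p-distance between two star-tree tips at rate r] = 2r - (4/3) r^2
    if d <= 0:
        return 0.0
    return (3.0 - np.sqrt(9.0 - 12.0 * d)) / 4.0


def _p_from_corrected(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected mismatch fraction at
    evolutionary distance d.  Diameter targets are specified on the corrected
    scale (the scale on which clustering thresholds and the VI-cut diameter
    bound operate); sequences are simulated in p-distance space."""
    return 0.75 * (1.0 - float(np.exp(-4.0 * d / 3.0)))


def _species_block(
    ancestor: np.ndarray,
    k: int,
    target: float,
    rng: np.random.Generator,
    cap: float | None = None,
) -> np.ndarray:
    """Draw k sequences around `ancestor` so the realized max pairwise
    p-distance approximates `target` without exceeding `cap`.

    The substitution rate starts at the closed-form solution for the expected
    pairwise distance and is refined multiplicatively a few times, because the
    maximum over all pairs sits above the mean, increasingly so for small
    targets.  The cap keeps the community's realized diameter range equal to
    the configured range (the stated study condition), not merely centred on
    it.  The loop is deterministic given the generator state.
    """
    if k == 1 or target <= 0:
        return np.tile(ancestor, (max(k, 1), 1))
    rate = _rate_for_diameter(target)
    best, best_err = None, np.inf
    for _ in range(8):
        block = np.stack([_mutate(ancestor, rate, rng) for _ in range(k)])
        realized = float(p_distance_matrix(block).max())
        if cap is not None and realized > cap:
            rate = max(rate * 0.9 * cap / realized, 0.0)
            continue
        err = abs(realized - target) / target
        if err < best_err:
            best, best_err = block, err
        if err <= 0.15:
            break
        if realized <= 0:
            rate = min(rate * 2 + 1.0 / ancestor.size, 0.45)
        else:
            rate = min(max(rate * target / realized, 0.0), 0.45)
    while best is None:  # every draw exceeded the cap; shrink until one fits
        rate *= 0.6
        block = np.stack([_mutate(ancestor, rate, rng) for _ in range(k)])
        if cap is None or float(p_distance_matrix(block).max()) <= cap or rate < 1e-9:
            best = block
    return best


def _assign_children(
    n_children: int, n_parents: int, rng: np.random.Generator
) -> np.ndarray:
    """Random surjective map child index -> parent index (every parent used)."""
    parents = np.concatenate(
        [
            rng.permutation(n_parents),
            rng.integers(0, n_parents, size=n_children - n_parents),
        ]
    )
    return parents[:n_children]


def _geometric_counts(total: int, n: int, skew: float) -> np.ndarray:
    """Apportion `total` into `n` geometric-decay counts with a floor of 1."""
    w = skew ** np.arange(n)
    raw = total * w / w.sum()
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    # largest-remainder adjustment toward the exact total
    while counts.sum() > total:
        i = int(np.argmax(counts))
        counts[i] -= 1
    rem = raw - np.floor(raw)
    order = np.argsort(-rem)
    i = 0
    while counts.sum() < total:
        counts[order[i % n]] += 1
        i += 1
    return counts


# ---------------------------------------------------------------------------
# public operations


def generate_community(
    config: CommunityConfig,
    return_details: bool = False,
):
    """Simulate a gap-free aligned community with consistent taxonomy.

    Deterministic given ``config.seed``.  Species ancestors are evolved down a
    random rank hierarchy; within each species, sequences radiate from the
    ancestor with a substitution rate calibrated so the realized diameter
    tracks its drawn target.  Confusable pairs get ancestors placed at
    p-distance ``0.5 * diameter_max`` of each other, below the widest species
    diameter in the community.

    With ``return_details=True`` a third element is returned: a dict with the
    per-species ``diameter_targets``, the ``confusable_pairs`` (species label
    pairs) and the per-species ``abundance`` counts.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("hierarchy", "ancestors", "targets", "species"), ss.spawn(4)
        )
    }
    L = config.alignment_length
    S = config.n_species
    lo, hi = config.species_diameter_range

    # --- rank hierarchy -----------------------------------------------------
    shape = (*config.rank_tree_shape, S)
    parent_of: list[np.ndarray] = []  # per level>0: child index -> parent index
    for lvl in range(1, 6):
        parent_of.append(
            _assign_children(shape[lvl], shape[lvl - 1], streams["hierarchy"])
        )

    def lineage(species_idx: int) -> dict[str, str]:
        idx = species_idx
        out = {"species": f"S{species_idx + 1:02d}"}
        for lvl in range(5, 0, -1):
            idx = int(parent_of[lvl - 1][idx])
            rank = RANKS[lvl - 1]
            out[rank] = f"{_RANK_PREFIX[rank]}{idx + 1:02d}"
        return out

    # --- ancestors along the hierarchy --------------------------------------
    # Evolutionary rates vary across lineages, so each guide-tree edge gets
    # an independent lognormal rate multiplier; species edges are clipped
    # harder so sibling-species separations stay above the diameter range
    # (only the explicit confusable pairs may dip below it).
    rng_anc = streams["ancestors"]
    root = rng_anc.integers(0, 4, size=L).astype(np.uint8)

    def edge_factor(rank: str) -> float:
        lo_f, hi_f = (0.7, 2.0) if rank == "species" else (0.6, 2.2)
        return float(np.clip(rng_anc.lognormal(mean=-0.06, sigma=0.35), lo_f, hi_f))

    level_seqs: list[np.ndarray] = [
        np.stack(
            [
                _mutate(root, _RANK_EDGE_RATES["phylum"] * edge_factor("phylum"), rng_anc)
                for _ in range(shape[0])
            ]
        )
    ]
    for lvl in range(1, 6):
        rank = RANKS[lvl]
        rate = (
            config.between_species_divergence / 2.0
            if rank == "species"
            else _RANK_EDGE_RATES[rank]
        )
        prev = level_seqs[-1]
        level_seqs.append(
            np.stack(
                [
                    _mutate(
                        prev[parent_of[lvl - 1][i]], rate * edge_factor(rank), rng_anc
                    )
                    for i in range(shape[lvl])
                ]
            )
        )
    species_anc = level_seqs[-1]

    # --- confusable pairs ----------------------------------------------------
    rng_t = streams["targets"]
    genus_of = parent_of[-1]
    sibling_pairs = [
        pair
        for g in range(shape[4])
        for pair in itertools.combinations(np.flatnonzero(genus_of == g).tolist(), 2)
    ]
    rng_t.shuffle(sibling_pairs)
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for a, b in sibling_pairs:
        if len(pairs) == config.n_confusable_pairs:
            break
        if a not in used and b not in used:
            pairs.append((a, b))
            used.update((a, b))
    free = [s for s in range(S) if s not in used]
    while len(pairs) < config.n_confusable_pairs:
        a, b = free.pop(0), free.pop(0)
        pairs.append((a, b))
        used.update((a, b))
    for a, b in pairs:
        species_anc[b] = _mutate(species_anc[a], 0.5 * _p_from_corrected(hi), rng_t)

    # --- per-species diameter targets (corrected scale) ----------------------
    targets = rng_t.uniform(lo, hi, size=S)
    for a, b in pairs:
        targets[a] = targets[b] = lo
    free_species = [s for s in range(S) if s not in used]
    if free_species:
        # pin one unconfused species at the widest diameter so the range is
        # fully expressed; the median-abundance one, so diameter and
        # abundance stay uncoupled (species are indexed by abundance rank)
        targets[free_species[len(free_species) // 2]] = hi
    p_targets = np.array([_p_from_corrected(t) for t in targets])

    # --- abundances -----------------------------------------------------------
    if config.abundance_counts is not None:
        counts = np.asarray(config.abundance_counts, dtype=int)
    else:
        counts = _geometric_counts(config.total_sequences, S, config.abundance_skew)

    # --- emit sequences -------------------------------------------------------
    ids: list[str] = []
    rows: list[str] = []
    tax_rows: list[dict[str, str]] = []
    species_streams = np.random.SeedSequence(config.seed).spawn(4)[3].spawn(S)
    for s in range(S):
        rng_s = np.random.default_rng(species_streams[s])
        block = _species_block(
            species_anc[s],
            int(counts[s]),
            float(p_targets[s]),
            rng_s,
            cap=_p_from_corrected(hi),
        )
        lin = lineage(s)
        for j in range(block.shape[0]):
            sid = f"S{s + 1:02d}_{j + 1:04d}"
            ids.append(sid)
            rows.append(decode_row(block[j]))
            tax_rows.append({"id": sid, **lin})

    seqs = AlignedSequenceSet(tuple(ids), tuple(rows))
    table = pd.DataFrame(tax_rows).set_index("id")[list(RANKS)]
    taxonomy = TaxonomyAnnotation(table)
    if not return_details:
        return seqs, taxonomy
    details = {
        "diameter_targets": {f"S{s + 1:02d}": float(targets[s]) for s in range(S)},
        "p_diameter_targets": {
            f"S{s + 1:02d}": float(p_targets[s]) for s in range(S)
        },
        "confusable_pairs": [(f"S{a + 1:02d}", f"S{b + 1:02d}") for a, b in pairs],
        "abundance": {f"S{s + 1:02d}": int(counts[s]) for s in range(S)},
    }
    return seqs, taxonomy, details


def subsample_community(
    seqs: AlignedSequenceSet,
    taxonomy: TaxonomyAnnotation,
    n: int,
    seed: int,
) -> tuple[AlignedSequenceSet, TaxonomyAnnotation]:
    """Uniformly sample `n` sequences without replacement, labels carried over."""
    if n > len(seqs):
        raise ValueError(f"cannot sample {n} from {len(seqs)} sequences")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(seqs), size=n, replace=False))
    ids = tuple(seqs.ids[i] for i in keep)
    rows = tuple(seqs.rows[i] for i in keep)
    table = taxonomy.table.loc[list(ids)]
    return AlignedSequenceSet(ids, rows), TaxonomyAnnotation(table)


def perturb_alignment_variant(
    seqs: AlignedSequenceSet, column_jitter_rate: float, seed: int
) -> AlignedSequenceSet:
    """Emulate the disagreement between alignment programs by gap jitter.

    At ``round(rate * n_columns)`` random positions, a one-column gap is
    inserted for a random subset of the rows and at a nearby offset for the
    remaining rows, locally shifting the register of the alignment without
    changing any row's ungapped content.  ``rate=0`` returns the input
    unchanged.
    """
    if not (0.0 <= column_jitter_rate < 1.0):
        raise ValueError("column_jitter_rate must be in [0, 1)")
    if column_jitter_rate == 0.0 or not seqs.rows:
        return AlignedSequenceSet(seqs.ids, seqs.rows)
    rng = np.random.default_rng(seed)
    n = len(seqs)
    work = [bytearray(r, "ascii") for r in seqs.rows]
    n_events = int(round(column_jitter_rate * seqs.n_columns))
    for _ in range(n_events):
        L = len(work[0])
        pos = int(rng.integers(0, L))
        window = int(rng.integers(1, 9))
        group_a = rng.random(n) < 0.5
        if group_a.all():
            group_a[int(rng.integers(0, n))] = False
        elif not group_a.any():
            group_a[int(rng.integers(0, n))] = True
        pos_b = min(pos + window, L)
        for i in range(n):
            work[i].insert(pos if group_a[i] else pos_b, ord("-"))
    rows = tuple(w.decode("ascii") for w in work)
    # drop any column that became all-gap
    codes = encode_rows(list(rows))
    keep = (codes < 4).any(axis=0)
    if not keep.all():
        rows = tuple(
            "".join(ch for ch, k in zip(r, keep) if k) for r in rows
        )
    return AlignedSequenceSet(seqs.ids, rows)


def mask_columns(seqs: AlignedSequenceSet, mask: np.ndarray) -> AlignedSequenceSet:
    """Keep only the columns flagged True, in their original order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != seqs.n_columns:
        raise ValueError(
            f"mask length {mask.size} != alignment columns {seqs.n_columns}"
        )
    if not mask.any():
        raise ValueError("mask retains no columns")
    idx = np.flatnonzero(mask)
    rows = tuple("".join(r[i] for i in idx) for r in seqs.rows)
    return AlignedSequenceSet(seqs.ids, rows)


# ---------------------------------------------------------------------------
# file interchange


def write_fasta(seqs: AlignedSequenceSet, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as bio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(seqs.ids, seqs.rows)
    ]
    bio_write(records, str(path), "fasta")


def read_fasta(path) -> AlignedSequenceSet:
    from Bio.SeqIO import parse as bio_parse

    ids, rows = [], []
    for rec in bio_parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignedSequenceSet(tuple(ids), tuple(rows))


def write_taxonomy(taxonomy: TaxonomyAnnotation, path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path) -> TaxonomyAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="id", dtype=str)
    return TaxonomyAnnotation(table)


def write_mask(mask: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("".join("1" if b else "0" for b in np.asarray(mask, bool)))
        fh.write("\n")


def read_mask(path) -> np.ndarray:
    with open(path) as fh:
        line = fh.read().strip()
    return np.array([c == "1" for c in line], dtype=bool)


def write_config(config: CommunityConfig, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_config(path) -> CommunityConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("species_diameter_range", "rank_tree_shape", "abundance_counts"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    return CommunityConfig(**data)
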