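"""Pairwise evolutionary distances with JC, K2P and F84 corrections.

Distances follow PHYLIP DNADIST conventions: sites where either sequence has
a gap (or an ambiguity code) are excluded pair by pair (pairwise deletion),
and the F84 correction uses empirical base frequencies pooled over the whole
alignment.  The corrections:

* Jukes-Cantor:      d = -(3/4) ln(1 - 4p/3)
* Kimura 2-parameter: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
* F84 (method of moments, with frequencies pi_A..pi_T, R = pi_A + pi_G,
  Y = pi_C + pi_T, A = pi_C pi_T / Y + pi_A pi_G / R, B = pi_C pi_T +
  pi_A pi_G, C = R Y):
      d = -2A ln(1 - P/(2A) - (A - B) Q / (2AC)) + 2(A - B - C) ln(1 - Q/(2C))

where p is the mismatch fraction, P the transition fraction and Q the
transversion fraction over compared sites.  All three agree with
``ape::dist.dna`` to machine precision and reduce to one another in the
appropriate limits (F84 -> K2P at uniform frequencies; K2P -> JC when
P = p/3, Q = 2p/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._seq import encode_rows
from .synthetic import AlignedSequenceSet

CORRECTIONS = ("NONE", "JC", "K2P", "F84")


class SaturationError(ValueError):
    """Observed divergence outside the domain of a distance correction."""


@dataclass(frozen=True)
class PairCounts:
    """Site counts for one pair of aligned rows (pairwise deletion applied)."""

    n_compared: int
    n_transitions: int
    n_transversions: int
    base_frequencies: tuple[float, float, float, float]  # A, C, G, T

    @property
    def p(self) -> float:
        return (self.n_transitions + self.n_transversions) / self.n_compared

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of fractional distances with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal is not zero")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("entries must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}

    def submatrix(self, ids: Iterable[str]) -> np.ndarray:
        pos = self.index()
        idx = np.array([pos[i] for i in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]


def pair_counts(row_a: str, row_b: str) -> PairCounts:
    """Count compared sites, transitions and transversions for two rows.

    Any site where either row is a gap or an ambiguity code is excluded from
    every count.  Base frequencies are tallied over the compared material of
    the two rows.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    codes = encode_rows([row_a, row_b])
    a, b = codes[0], codes[1]
    valid = (a < 4) & (b < 4)
    nc = int(valid.sum())
    if nc == 0:
        raise ValueError("no comparable sites between the two rows")
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int(diff.sum()) - ts
    pooled = np.concatenate([a[valid], b[valid]])
    freqs = np.bincount(pooled, minlength=4)[:4] / (2.0 * nc)
    # codes are A,G,C,T -> reorder to A,C,G,T
    fa, fg, fc, ft = freqs
    return PairCounts(nc, ts, tv, (float(fa), float(fc), float(fg), float(ft)))


def jc_correct(p):
    """Jukes-Cantor correction of a mismatch fraction (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 0.75):
        raise SaturationError("JC correction requires 0 <= p < 0.75")
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return float(d) if d.ndim == 0 else d


def k2p_correct(P, Q):
    """Kimura 2-parameter correction from transition/transversion fractions."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        raise SaturationError("K2P correction outside its domain")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return float(d) if d.ndim == 0 else d


def f84_correct(counts: PairCounts, base_frequencies=None) -> float:
    """F84 maximum-likelihood (method of moments) distance for one pair.

    By default uses the pair's own pooled base frequencies; pass
    `base_frequencies` (A, C, G, T) to use alignment-wide frequencies as
    DNADIST does.
    """
    freqs = base_frequencies if base_frequencies is not None else counts.base_frequencies
    d = _f84_from_fractions(counts.P, counts.Q, freqs)
    return float(d)


def _f84_from_fractions(P, Q, freqs):
    fa, fc, fg, ft = (float(x) for x in freqs)
    R = fa + fg
    Y = fc + ft
    if R <= 0 or Y <= 0:
        raise SaturationError("degenerate base composition for F84")
    A = fc * ft / Y + fa * fg / R
    B = fc * ft + fa * fg
    C = R * Y
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    w1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    w2 = 1.0 - Q / (2.0 * C)
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        raise SaturationError("F84 correction outside its domain")
    d = -2.0 * A * np.log(w1) + 2.0 * (A - B - C) * np.log(w2)
    return float(d) if d.ndim == 0 else d


def alignment_base_frequencies(seqs: AlignedSequenceSet) -> tuple[float, float, float, float]:
    """Empirical A, C, G, T fractions over all non-gap sites of the alignment."""
    codes = seqs.to_codes()
    flat = codes[codes < 4]
    if flat.size == 0:
        raise ValueError("alignment has no nucleotide content")
    fa, fg, fc, ft = np.bincount(flat, minlength=4)[:4] / flat.size
    return (float(fa), float(fc), float(fg), float(ft))


def distance_matrix(
    seqs: AlignedSequenceSet,
    correction: str = "JC",
    on_saturation: str = "raise",
    cap: float = 5.0,
) -> DistanceMatrix:
    """All-pairs distances under one correction, with pairwise deletion.

    ``correction="NONE"`` returns raw p-distances.  When a pair falls outside
    the correction's domain the default is to raise :class:`SaturationError`
    naming the pair; ``on_saturation="cap"`` clips such pairs to ``cap``
    substitutions per site instead (useful in robustness sweeps, but
    distorting for clustering — see docs).
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    if on_saturation not in ("raise", "cap"):
        raise ValueError("on_saturation must be 'raise' or 'cap'")
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    codes = seqs.to_codes()
    n = codes.shape[0]
    valid = codes < 4
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n - 1):
        vi = valid[i] & valid[i + 1 :]
        nc = vi.sum(axis=1)
        if np.any(nc == 0):
            j = int(np.argmax(nc == 0)) + i + 1
            raise ValueError(
                f"no comparable sites between {seqs.ids[i]!r} and {seqs.ids[j]!r}"
            )
        diff = vi & (codes[i] != codes[i + 1 :])
        ts = (diff & ((codes[i] >> 1) == (codes[i + 1 :] >> 1))).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        P[i, i + 1 :] = ts / nc
        Q[i, i + 1 :] = tv / nc
    P += P.T
    Q += Q.T

    iu = np.triu_indices(n, k=1)
    p_flat, P_flat, Q_flat = (P + Q)[iu], P[iu], Q[iu]
    try:
        if correction == "NONE":
            d_flat = p_flat.copy()
        elif correction == "JC":
            d_flat = _corrected_or_cap(
                p_flat, lambda x: jc_correct(x), x_domain=p_flat < 0.75,
                on_saturation=on_saturation, cap=cap,
            )
        elif correction == "K2P":
            dom = (1 - 2 * P_flat - Q_flat > 0) & (1 - 2 * Q_flat > 0)
            d_flat = _corrected_or_cap(
                (P_flat, Q_flat), lambda x: k2p_correct(*x), x_domain=dom,
                on_saturation=on_saturation, cap=cap,
            )
        else:  # F84
            freqs = alignment_base_frequencies(seqs)
            fa, fc, fg, ft = freqs
            R, Y = fa + fg, fc + ft
            A = fc * ft / Y + fa * fg / R
            B = fc * ft + fa * fg
            C = R * Y
            dom = (1 - P_flat / (2 * A) - (A - B) * Q_flat / (2 * A * C) > 0) & (
                1 - Q_flat / (2 * C) > 0
            )
            d_flat = _corrected_or_cap(
                (P_flat, Q_flat), lambda x: _f84_from_fractions(*x, freqs),
                x_domain=dom, on_saturation=on_saturation, cap=cap,
            )
    except SaturationError:
        pair = _first_saturated_pair(seqs.ids, iu, correction, P_flat, Q_flat)
        raise SaturationError(
            f"{correction} correction saturated for pair {pair}"
        ) from None

    values = np.zeros((n, n))
    values[iu] = d_flat
    values += values.T
    return DistanceMatrix(tuple(seqs.ids), values)


def _corrected_or_cap(x, func, x_domain, on_saturation, cap):
    if np.all(x_domain):
        return np.asarray(func(x), dtype=float)
    if on_saturation == "raise":
        raise SaturationError("saturated pair")
    xt = (
        tuple(np.where(x_domain, xi, 0.0) for xi in x)
        if isinstance(x, tuple)
        else np.where(x_domain, x, 0.0)
    )
    out = np.asarray(func(xt), dtype=float)
    out[~x_domain] = cap
    return out


def _first_saturated_pair(ids, iu, correction, P_flat, Q_flat):
    if correction == "JC":
        bad = P_flat + Q_flat >= 0.75
    else:
        bad = (1 - 2 * P_flat - Q_flat <= 0) | (1 - 2 * Q_flat <= 0)
    k = int(np.argmax(bad))
    return (ids[iu[0][k]], ids[iu[1][k]])


# ---------------------------------------------------------------------------
# PHYLIP square matrix interchange


def write_phylip(dm: DistanceMatrix, path, precision: int = 6) -> None:
    """Write a relaxed PHYLIP square distance matrix (whitespace-delimited)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for sid, row in zip(dm.ids, dm.values):
            vals = " ".join(f"{v:.{precision}f}" for v in row)
            fh.write(f"{sid} {vals}\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix, strict or relaxed dialect.

    Strict rows pad the name to 10 characters (possibly containing spaces);
    relaxed rows are whitespace-delimited.  Rows may wrap onto continuation
    lines.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    ids: list[str] = []
    rows: list[list[float]] = []
    k = 1
    while len(rows) < n:
        line = lines[k]
        k += 1
        tokens = line.split()
        try:
            vals = [float(t) for t in tokens[1:]]
            name = tokens[0]
        except ValueError:
            name = line[:10].strip()
            vals = [float(t) for t in line[10:].split()]
        while len(vals) < n:
            vals.extend(float(t) for t in lines[k].split())
            k += 1
        if len(vals) != n:
            raise ValueError(f"row {name!r} has {len(vals)} values, expected {n}")
        ids.append(name)
        rows.append(vals)
    values = np.array(rows, dtype=float)
    values = (values + values.T) / 2.0  # symmetrize away printed rounding
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(ids), values)
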