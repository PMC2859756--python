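"""Nonparametric richness estimators and the Shannon diversity index.

Operates on OTU abundance vectors (per-cluster sequence counts).  Writing
S_obs for the number of observed OTUs, F_i for the number of OTUs seen
exactly i times and N for the total count:

* Chao1 (classic):        S_obs + F1^2 / (2 F2);
  bias-corrected fallback S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0
  (or on request).
* ACE, with "rare" OTUs those of <= `rare_cutoff` (default 10) members:
  C_ace = 1 - F1 / N_rare, gamma^2 = max[(S_rare / C_ace)
  * sum_i i (i-1) F_i / (N_rare (N_rare - 1)) - 1, 0], and
  S_ace = S_abund + S_rare / C_ace + (F1 / C_ace) gamma^2.
  When every rare OTU is a singleton C_ace = 0 and ACE is undefined; the
  bias-corrected Chao1 is returned instead with a warning.
* Shannon: H = -sum (n_i / N) ln(n_i / N), natural log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import Clustering


@dataclass(frozen=True)
class AbundanceVector:
    """Per-OTU positive counts, order-stable."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts or any(c < 1 for c in self.counts):
            raise ValueError("counts must be positive integers")

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    @property
    def S_obs(self) -> int:
        return len(self.counts)

    def F(self, i: int) -> int:
        """Number of OTUs observed exactly i times."""
        return int(sum(1 for c in self.counts if c == i))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def abundances(C: Clustering) -> AbundanceVector:
    """Cluster sizes as an abundance vector (ordered by first member id)."""
    return AbundanceVector(tuple(len(c) for c in C.clusters))


def chao1(a: AbundanceVector, bias_corrected: bool | None = None) -> float:
    """Chao1 richness estimate.

    `bias_corrected=None` (default) uses the classic form and falls back to
    the bias-corrected form only when F2 = 0; True forces the bias-corrected
    form; False forces the classic form (error when F2 = 0 and F1 > 0).
    """
    f1, f2 = a.F(1), a.F(2)
    if bias_corrected is None:
        bias_corrected = f2 == 0
    if bias_corrected:
        return a.S_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined when F2 = 0")
    return a.S_obs + f1 * f1 / (2.0 * f2)


def ace(a: AbundanceVector, rare_cutoff: int = 10) -> float:
    """ACE richness estimate (abundance-based coverage estimator)."""
    counts = a.as_array()
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(a.S_obs)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "all rare OTUs are singletons; ACE undefined, falling back to "
            "bias-corrected Chao1",
            stacklevel=2,
        )
        return chao1(a, bias_corrected=True)
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([(rare == k).sum() for k in i])
    sum_iif = float((i * (i - 1) * fi).sum())
    gamma2 = (s_rare / c_ace) * sum_iif / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(a: AbundanceVector) -> float:
    """Shannon diversity H in natural-log units; 0 for a single OTU."""
    p = a.as_array() / a.N
    return float(max(-(p * np.log(p)).sum(), 0.0))


def diversity_report_row(D: float, C: Clustering) -> dict:
    """One row of a per-clustering diversity table."""
    a = abundances(C)
    return {
        "D": D,
        "n_OTUs": C.n_clusters,
        "S_obs": a.S_obs,
        "chao1": chao1(a),
        "ace": ace(a),
        "shannon": shannon(a),
    }
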