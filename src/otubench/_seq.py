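"""Shared low-level sequence encoding and p-distance kernels.

Nucleotides are encoded as uint8 codes A=0, G=1, C=2, T=3 so that purines and
pyrimidines share the high bit (code >> 1 gives 0 for purines, 1 for
pyrimidines).  Gaps and ambiguity codes map to NON_BASE and are excluded from
every pairwise comparison (pairwise deletion).
"""

from __future__ import annotations

import numpy as np

NON_BASE: int = 255

_CODE = np.full(256, NON_BASE, dtype=np.uint8)
for _i, _ch in enumerate("AGCT"):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i

_CHAR = np.array(list("AGCT"), dtype="<U1")


def encode_rows(rows: list[str]) -> np.ndarray:
    """Encode equal-length gapped strings into a (n, L) uint8 code matrix."""
    if not rows:
        return np.empty((0, 0), dtype=np.uint8)
    buf = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(rows), len(rows[0]))


def decode_row(codes: np.ndarray) -> str:
    """Decode a 1-D code vector back to a string ('-' for non-bases)."""
    out = np.where(codes < 4, _CHAR[np.minimum(codes, 3)], "-")
    return "".join(out.tolist())


def p_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Symmetric matrix of uncorrected mismatch fractions (pairwise deletion).

    Raises ValueError if some pair shares no comparable site.
    """
    n = codes.shape[0]
    valid = codes < 4
    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        vi = valid[i] & valid[i + 1 :]
        nc = vi.sum(axis=1)
        if np.any(nc == 0):
            j = int(np.argmax(nc == 0)) + i + 1
            raise ValueError(f"no comparable sites between rows {i} and {j}")
        nd = (vi & (codes[i] != codes[i + 1 :])).sum(axis=1)
        out[i, i + 1 :] = nd / nc
    out += out.T
    return out
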