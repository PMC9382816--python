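"""Protein scoring matrices and Karlin-Altschul statistics.

The default scoring system mirrors the common translated-search
defaults: BLOSUM62 with affine gap penalties 11 (open) / 1 (extend).
Karlin-Altschul parameters (lambda, K, H) are hard-coded for that
system, gapped and ungapped; other matrices fall back to the ungapped
estimates, which is documented as an approximation.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET: str = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
SUBMAT: np.ndarray = np.asarray(_BLOSUM62, dtype=np.int16)

_X_IDX = AA_ALPHABET.index("X")
AA_ENCODE = np.full(256, _X_IDX, dtype=np.uint8)
for _i, _c in enumerate(AA_ALPHABET):
    AA_ENCODE[ord(_c)] = _i


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string into BLOSUM62 row indices.

    Characters outside the matrix alphabet (J, U, O, ...) map to X.
    """
    return AA_ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# (lambda, K, H) for BLOSUM62; gapped values are for open/extend = 11/1.
KA_UNGAPPED = (0.3176, 0.134, 0.4012)
KA_GAPPED_11_1 = (0.267, 0.041, 0.14)

LN2 = math.log(2.0)


def karlin_altschul(gapped: bool, gap_open: int = 11, gap_extend: int = 1):
    if not gapped:
        return KA_UNGAPPED
    if (gap_open, gap_extend) == (11, 1):
        return KA_GAPPED_11_1
    # other gap settings: fall back to ungapped estimates (documented)
    return KA_UNGAPPED


def bitscore(raw: float, gapped: bool, gap_open: int = 11, gap_extend: int = 1) -> float:
    lam, k, _ = karlin_altschul(gapped, gap_open, gap_extend)
    return (lam * raw - math.log(k)) / LN2


@lru_cache(maxsize=4096)
def _length_adjustment(m: int, n: int, gapped: bool, gap_open: int, gap_extend: int) -> float:
    lam, k, h = karlin_altschul(gapped, gap_open, gap_extend)
    if m <= 0 or n <= 0:
        return 0.0
    return max(0.0, math.log(k * m * n) / h)


def evalue(
    raw: float,
    query_len: int,
    db_len: int,
    n_seqs: int = 1,
    gapped: bool = True,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Expected number of chance hits with score >= ``raw``.

    Effective search space is (m - l) * (N - n_seqs * l) with the
    standard logarithmic length adjustment l; both factors are floored
    at 1.
    """
    ladj = _length_adjustment(query_len, db_len, gapped, gap_open, gap_extend)
    m_eff = max(query_len - ladj, 1.0)
    n_eff = max(db_len - n_seqs * ladj, 1.0)
    bits = bitscore(raw, gapped, gap_open, gap_extend)
    return m_eff * n_eff * math.pow(2.0, -bits)
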