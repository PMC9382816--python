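"""Numba-compiled inner loops of the alignment engine.

Everything here operates on small integer-encoded arrays: nucleotides
as 0..4 (A,C,G,T,N), amino acids as BLOSUM62 row indices. The public
API lives in :mod:`viromine.homology`; these kernels are deliberately
free of any Python object handling so they compile to tight machine
code.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def longest_border(arr: np.ndarray) -> int:
    """Length of the longest proper prefix of ``arr`` that is also a
    suffix (KMP prefix function, last value). Used for terminal
    direct-repeat detection on contigs."""
    n = arr.shape[0]
    if n == 0:
        return 0
    pi = np.zeros(n, np.int64)
    k = 0
    for i in range(1, n):
        while k > 0 and arr[i] != arr[k]:
            k = pi[k - 1]
        if arr[i] == arr[k]:
            k += 1
        pi[i] = k
    return int(pi[n - 1])


@njit(cache=True)
def sw_align(q, s, sub, gap_first, gap_extend):
    """Affine-gap Smith-Waterman with full traceback (Gotoh).

    ``gap_first`` is the cost of the first residue of a gap (open +
    extend in the common aligner convention, i.e. 12 for 11/1).

    Returns (score, q_start, q_end, s_start, s_end, n_ident,
    n_mismatch, gap_opens, aln_len) with 0-based half-open coordinates.
    A score of 0 means no positive-scoring local alignment exists.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = -(1 << 30)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    ptrH = np.zeros((m + 1, n + 1), np.uint8)
    ptrE = np.zeros((m + 1, n + 1), np.uint8)
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_first
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_first
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    i = bi
    j = bj
    nident = 0
    mism = 0
    gapopens = 0
    alnlen = 0
    state = 0
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                alnlen += 1
                if q[i - 1] == s[j - 1]:
                    nident += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # gap in query: consume subject column
            alnlen += 1
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                gapopens += 1
                state = 0
        else:  # gap in subject: consume query row
            alnlen += 1
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                gapopens += 1
                state = 0
    return best, i, bi, j, bj, nident, mism, gapopens, alnlen


@njit(cache=True)
def extend_seeds(qenc, scat, soff, seed_sid, seed_q, seed_s, sub, word, xdrop, min_raw, out):
    """Ungapped X-drop extension of exact word seeds.

    ``qenc`` is one encoded query (a translation frame); the subject
    side is a set of encoded sequences concatenated in ``scat`` with
    offsets ``soff`` (``soff[k]..soff[k+1]`` is subject ``k``). Seeds
    must be sorted by (subject id, diagonal, query position); seeds
    falling inside the extent of a previous extension on the same
    (subject, diagonal) are skipped, which is the standard one-hit
    dedup.

    Rows of ``out`` (int32, shape (n_seeds, 8)): subject id, q_start,
    q_end, s_start, s_end (0-based half-open, subject-local), raw
    score, n_ident, n_mismatch. Returns the number of rows written.
    """
    qlen = qenc.shape[0]
    nout = 0
    last_sid = -1
    last_diag = -(1 << 60)
    last_qend = -1
    for t in range(seed_q.shape[0]):
        sid = seed_sid[t]
        qpos = seed_q[t]
        spos = seed_s[t]
        diag = spos - qpos
        if sid == last_sid and diag == last_diag and qpos < last_qend:
            continue
        base = soff[sid]
        slen = soff[sid + 1] - base
        sc = 0
        for k in range(word):
            sc += sub[qenc[qpos + k], scat[base + spos + k]]
        # right extension
        gain = 0
        best_gain_r = 0
        ext_r = 0
        k = 0
        while qpos + word + k < qlen and spos + word + k < slen:
            gain += sub[qenc[qpos + word + k], scat[base + spos + word + k]]
            k += 1
            if gain > best_gain_r:
                best_gain_r = gain
                ext_r = k
            elif best_gain_r - gain > xdrop:
                break
        # left extension
        gain = 0
        best_gain_l = 0
        ext_l = 0
        k = 1
        while qpos - k >= 0 and spos - k >= 0:
            gain += sub[qenc[qpos - k], scat[base + spos - k]]
            if gain > best_gain_l:
                best_gain_l = gain
                ext_l = k
            elif best_gain_l - gain > xdrop:
                break
            k += 1
        score = sc + best_gain_r + best_gain_l
        qs = qpos - ext_l
        qe = qpos + word + ext_r
        ss = spos - ext_l
        se = spos + word + ext_r
        last_sid = sid
        last_diag = diag
        last_qend = qe
        if score >= min_raw:
            nident = 0
            for k in range(qe - qs):
                if qenc[qs + k] == scat[base + ss + k]:
                    nident += 1
            out[nout, 0] = sid
            out[nout, 1] = qs
            out[nout, 2] = qe
            out[nout, 3] = ss
            out[nout, 4] = se
            out[nout, 5] = score
            out[nout, 6] = nident
            out[nout, 7] = (qe - qs) - nident
            nout += 1
    return nout
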