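"""Desk-scale translated local-alignment engine.

Implements the searches the recruitment and mining stages need without
shelling out to an external aligner:

* protein query vs six-frame-translated DNA database (tblastn-like),
* DNA query vs protein database, best hit only (blastx-like),
* genome vs genome in all 6x6 frame pairs, ungapped HSPs (tblastx-like,
  used for the SG genome-similarity score),
* exact nucleotide k-mismatch scanning (for CRISPR protospacers).

The gapped searches seed with word-window scores over the BLOSUM62
profile (exact 3-mers with a neighborhood threshold, the standard
translated-search heuristic) and then run a full affine-gap
Smith-Waterman over the seeded frame, or over a diagonal window of it
when the frame is large. The ungapped searches use exact-word hashing
plus X-drop extension. E-values come from Karlin-Altschul statistics
with hard-coded (lambda, K) for BLOSUM62 and an effective search-space
length adjustment; this is a documented approximation of what the
external aligners compute.

Tie-breaking everywhere is bitscore descending, then E-value ascending,
then subject id lexicographic, for determinism.

A standard 12-column tabular hit file ("outfmt 6" layout) can be read
and written, so any stage can be bypassed with an external aligner's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from . import _scoring
from ._kernels import extend_seeds, sw_align
from ._scoring import SUBMAT, bitscore as _bitscore, encode_aa, evalue as _evalue
from .errors import EmptyInputError, FormatError, ParameterError
from .seqio import (
    SequenceRecord,
    encode_nt,
    frame_to_forward,
    revcomp_enc,
    six_frame_translate,
    translate_enc,
)

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

# Cap on full-DP area per (query, frame); larger frames are aligned in
# diagonal windows around the seeds.
MAX_FULL_CELLS = 4_000_000


@dataclass
class SearchParams:
    """Parameters of a translated search.

    Defaults mirror the common aligner invocation this engine stands in
    for: E-value cutoff 1e-3, BLOSUM62 with gaps 11/1, word size 3 with
    neighborhood threshold 11, identity floor 30%, low-complexity
    filtering off.
    """

    evalue_max: float = 1e-3
    word_size: int = 3
    min_identity_pct: float = 30.0
    max_targets: int = 1_000_000
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    seed_threshold: int = 11
    xdrop: int = 16
    low_complexity_filter: bool = False

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ParameterError("evalue_max must be > 0")
        if not 0 <= self.min_identity_pct <= 100:
            raise ParameterError("min_identity_pct must be in [0, 100]")
        if self.word_size < 2:
            raise ParameterError("word_size must be >= 2")
        if self.matrix != "BLOSUM62":
            raise ParameterError("only BLOSUM62 is built in")
        if self.low_complexity_filter:
            raise ParameterError("low-complexity filtering is not implemented (off by design)")

    @property
    def gap_first(self) -> int:
        """Cost of the first residue of a gap (open + extend)."""
        return self.gap_open + self.gap_extend


@dataclass
class AlignmentHit:
    """One local alignment, mirroring the 12 standard tabular columns
    plus the translation frame and the raw alignment score."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    frame: int | None = None
    raw_score: int | None = None

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ParameterError("percent_identity out of [0, 100]")
        if self.aln_length < 1:
            raise ParameterError("aln_length must be >= 1")
        if self.evalue < 0 or self.bitscore <= 0:
            raise ParameterError("need evalue >= 0 and bitscore > 0")


def _hit_sort_key(h: AlignmentHit):
    return (-h.bitscore, h.evalue, h.subject_id, h.q_start, h.s_start)


# ---------------------------------------------------------------------------
# seeding + gapped alignment of one (query, frame) pair
# ---------------------------------------------------------------------------

def _window_seeds(qenc: np.ndarray, senc: np.ndarray, word: int, threshold: int):
    """Positions (q, s) where the ``word``-long diagonal window of the
    BLOSUM62 profile scores >= ``threshold`` (seed pairs, neighborhood
    scoring included by construction)."""
    qm = len(qenc) - word + 1
    sm = len(senc) - word + 1
    if qm <= 0 or sm <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    # chunk the subject axis to bound memory
    chunk = max(1, int(8_000_000 // max(qm, 1)))
    qs_all: list[np.ndarray] = []
    ss_all: list[np.ndarray] = []
    for j0 in range(0, sm, chunk):
        j1 = min(sm, j0 + chunk)
        prof = SUBMAT[qenc[:, None], senc[None, j0 : j1 + word - 1]].astype(np.int32)
        w = prof[:qm, : j1 - j0].copy()
        for k in range(1, word):
            w += prof[k : qm + k, k : j1 - j0 + k]
        qi, si = np.nonzero(w >= threshold)
        qs_all.append(qi.astype(np.int64))
        ss_all.append(si.astype(np.int64) + j0)
    return np.concatenate(qs_all), np.concatenate(ss_all)


def _frame_alignments(qenc: np.ndarray, senc: np.ndarray, params: SearchParams):
    """Seed a (query, frame) pair and run gapped Smith-Waterman; returns
    tuples (raw, qs, qe, ss, se, nident, mism, gapopens, alnlen) with
    0-based half-open coordinates on the two axes."""
    qs_arr, ss_arr = _window_seeds(qenc, senc, params.word_size, params.seed_threshold)
    if len(qs_arr) == 0:
        return []
    qlen, slen = len(qenc), len(senc)
    sub = SUBMAT
    results = []
    if qlen * slen <= MAX_FULL_CELLS:
        out = sw_align(qenc, senc, sub, params.gap_first, params.gap_extend)
        if out[0] > 0:
            results.append(out)
        return results
    # diagonal windows around seed clusters
    diags = np.sort(ss_arr - qs_arr)
    clusters: list[tuple[int, int]] = []
    lo = hi = int(diags[0])
    for d in diags[1:]:
        d = int(d)
        if d - hi <= 64:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    seen: set[tuple[int, int, int, int]] = set()
    for lo, hi in clusters:
        s_lo = max(0, lo - 16)
        s_hi = min(slen, hi + qlen + 16)
        if s_hi <= s_lo:
            continue
        out = sw_align(qenc, senc[s_lo:s_hi], sub, params.gap_first, params.gap_extend)
        if out[0] <= 0:
            continue
        raw, a, b, c, d_, nid, mm, go, al = out
        key = (a, b, c + s_lo, d_ + s_lo)
        if key in seen:
            continue
        seen.add(key)
        results.append((raw, a, b, c + s_lo, d_ + s_lo, nid, mm, go, al))
    return results


# ---------------------------------------------------------------------------
# public gapped searches
# ---------------------------------------------------------------------------

def search_protein_vs_dna(
    query: SequenceRecord,
    db: list[SequenceRecord],
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """tblastn-like search: protein query against six-frame translations
    of the nucleotide subjects. Subject coordinates are 1-based on the
    forward strand, with start > end for minus frames."""
    params = params or SearchParams()
    if len(query.seq) < params.word_size:
        raise ParameterError("query shorter than word_size")
    if not db:
        raise EmptyInputError("empty subject database")
    qenc = encode_aa(query.seq)
    frames_by_subject = [(subj, six_frame_translate(subj)) for subj in db]
    total_aa = sum(len(f) for _, fr in frames_by_subject for f in fr.values())
    nseq = 6 * len(db)
    hits: list[AlignmentHit] = []
    for subj, frames in frames_by_subject:
        for f in FRAME_ORDER:
            fenc = encode_aa(frames[f])
            for raw, a, b, c, d, nid, mm, go, al in _frame_alignments(qenc, fenc, params):
                pid = 100.0 * nid / al
                ev = _evalue(raw, len(query.seq), total_aa, nseq, True,
                             params.gap_open, params.gap_extend)
                if ev > params.evalue_max or pid < params.min_identity_pct:
                    continue
                s_start, s_end = frame_to_forward(f, c, d, len(subj.seq))
                hits.append(
                    AlignmentHit(
                        query.id, subj.id, pid, al, mm, go, a + 1, b,
                        s_start, s_end, ev,
                        _bitscore(raw, True, params.gap_open, params.gap_extend),
                        frame=f, raw_score=raw,
                    )
                )
    hits.sort(key=_hit_sort_key)
    return hits[: params.max_targets]


def search_dna_vs_protein(
    query: SequenceRecord,
    db: list[SequenceRecord],
    params: SearchParams | None = None,
) -> AlignmentHit | None:
    """blastx-like search returning the single best hit (or None).

    Query coordinates are on the DNA, start > end for minus frames;
    ties are broken by lower E-value, then lexicographically smallest
    subject id.
    """
    params = params or SearchParams()
    if len(query.seq) < 3 * params.word_size:
        raise ParameterError("query shorter than 3 * word_size nt")
    if not db:
        raise EmptyInputError("empty protein database")
    frames = six_frame_translate(query)
    total_aa = sum(len(p.seq) for p in db)
    best: AlignmentHit | None = None
    for subj in db:
        penc = encode_aa(subj.seq)
        for f in FRAME_ORDER:
            fenc = encode_aa(frames[f])
            for raw, a, b, c, d, nid, mm, go, al in _frame_alignments(fenc, penc, params):
                pid = 100.0 * nid / al
                ev = _evalue(raw, len(fenc), total_aa, len(db), True,
                             params.gap_open, params.gap_extend)
                if ev > params.evalue_max or pid < params.min_identity_pct:
                    continue
                q_start, q_end = frame_to_forward(f, a, b, len(query.seq))
                hit = AlignmentHit(
                    query.id, subj.id, pid, al, mm, go, q_start, q_end,
                    c + 1, d, ev,
                    _bitscore(raw, True, params.gap_open, params.gap_extend),
                    frame=f, raw_score=raw,
                )
                if best is None or _hit_sort_key(hit) < _hit_sort_key(best):
                    best = hit
    return best


# ---------------------------------------------------------------------------
# exact-word index + ungapped batch search (recruitment, SG)
# ---------------------------------------------------------------------------

class WordIndex:
    """Exact amino-acid word index over a set of encoded sequences."""

    def __init__(self, seqs_enc: list[np.ndarray], word: int = 4):
        self.word = word
        self.n_seqs = len(seqs_enc)
        lens = np.array([len(a) for a in seqs_enc], dtype=np.int64)
        self.soff = np.zeros(len(seqs_enc) + 1, dtype=np.int64)
        np.cumsum(lens, out=self.soff[1:])
        self.scat = (
            np.concatenate(seqs_enc) if seqs_enc else np.empty(0, np.uint8)
        ).astype(np.uint8)
        self.total_residues = int(lens.sum())
        codes_l, sid_l, pos_l = [], [], []
        for i, arr in enumerate(seqs_enc):
            n = len(arr) - word + 1
            if n <= 0:
                continue
            c = np.zeros(n, dtype=np.int64)
            for k in range(word):
                c *= 24
                c += arr[k : k + n]
            codes_l.append(c)
            sid_l.append(np.full(n, i, dtype=np.int64))
            pos_l.append(np.arange(n, dtype=np.int64))
        if codes_l:
            codes = np.concatenate(codes_l)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.occ_sid = np.concatenate(sid_l)[order]
            self.occ_pos = np.concatenate(pos_l)[order]
        else:
            self.codes = np.empty(0, np.int64)
            self.occ_sid = np.empty(0, np.int64)
            self.occ_pos = np.empty(0, np.int64)

    def lookup(self, qenc: np.ndarray):
        """Exact word matches of a query: arrays (q_pos, seq_id, s_pos)."""
        n = len(qenc) - self.word + 1
        empty = (np.empty(0, np.int64),) * 3
        if n <= 0 or len(self.codes) == 0:
            return empty
        qc = np.zeros(n, dtype=np.int64)
        for k in range(self.word):
            qc *= 24
            qc += qenc[k : k + n]
        left = np.searchsorted(self.codes, qc, side="left")
        right = np.searchsorted(self.codes, qc, side="right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            return empty
        qpos = np.repeat(np.arange(n, dtype=np.int64), counts)
        starts = np.repeat(left, counts)
        offs = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        occ = starts + offs
        return qpos, self.occ_sid[occ], self.occ_pos[occ]


def ungapped_hsps_vs_index(
    qenc: np.ndarray, index: WordIndex, xdrop: int = 20, min_raw: int = 35
) -> np.ndarray:
    """All ungapped X-drop HSPs of one encoded query against an indexed
    database. Returns an int32 array with rows (seq_id, q_start, q_end,
    s_start, s_end, raw, n_ident, n_mismatch)."""
    qpos, sid, spos = index.lookup(qenc)
    if len(qpos) == 0:
        return np.empty((0, 8), np.int32)
    order = np.lexsort((qpos, spos - qpos, sid))
    out = np.empty((len(qpos), 8), np.int32)
    n = extend_seeds(
        qenc, index.scat, index.soff, sid[order], qpos[order], spos[order],
        SUBMAT, index.word, xdrop, min_raw, out,
    )
    return out[:n]


class BatchHit(NamedTuple):
    """One ungapped translated HSP of a read against an indexed protein."""

    prot: int
    frame: int
    q_aa_start: int
    q_aa_end: int
    s_start: int  # protein, 0-based half-open
    s_end: int
    raw: int
    nident: int
    mismatches: int
    aln_length: int
    bitscore: float
    evalue: float


def batch_search_reads(
    reads: Iterable[SequenceRecord],
    index: WordIndex,
    params: SearchParams | None = None,
) -> list[list[BatchHit]]:
    """Translated search of many reads against an indexed protein set.

    For each read, the best HSP per protein (by raw score, then frame
    order) that passes the E-value and identity filters is returned.
    This is the ungapped fast path used by read recruitment; scores are
    directly comparable across proteins because the scoring system is
    shared.
    """
    params = params or SearchParams()
    results: list[list[BatchHit]] = []
    n_db = index.total_residues
    nseq = index.n_seqs
    for read in reads:
        fwd = encode_nt(read.seq)
        rev = revcomp_enc(fwd)
        best_per_prot: dict[int, BatchHit] = {}
        for f in FRAME_ORDER:
            arr = fwd[f - 1 :] if f > 0 else rev[-f - 1 :]
            aa = translate_enc(arr)
            if len(aa) < index.word:
                continue
            qenc = encode_aa(aa)
            rows = ungapped_hsps_vs_index(qenc, index, params.xdrop)
            m_aa = len(qenc)
            for sid, qs, qe, ss, se, raw, nid, mm in rows:
                al = int(qe - qs)
                pid = 100.0 * nid / al
                if pid < params.min_identity_pct:
                    continue
                ev = _evalue(int(raw), m_aa, n_db, nseq, gapped=False)
                if ev > params.evalue_max:
                    continue
                hit = BatchHit(
                    int(sid), f, int(qs), int(qe), int(ss), int(se), int(raw),
                    int(nid), int(mm), al, _bitscore(int(raw), gapped=False), ev,
                )
                prev = best_per_prot.get(hit.prot)
                if prev is None or hit.raw > prev.raw:
                    best_per_prot[hit.prot] = hit
        results.append([best_per_prot[k] for k in sorted(best_per_prot)])
    return results


class GenomeHsp(NamedTuple):
    """One ungapped HSP between two six-frame-translated genomes."""

    a_frame: int
    b_frame: int
    qs_aa: int
    qe_aa: int
    ss_aa: int
    se_aa: int
    q_nt_lo: int  # ordered 0-based half-open interval on genome A
    q_nt_hi: int
    raw: int
    nident: int
    bitscore: float
    evalue: float


def translated_genome_hsps(
    a: SequenceRecord,
    b: SequenceRecord,
    params: SearchParams | None = None,
    word_size: int = 4,
    min_raw: int = 35,
) -> list[GenomeHsp]:
    """tblastx-like all-frames-vs-all-frames ungapped HSP search between
    two genomes, E-value filtered. The backbone of the SG score."""
    params = params or SearchParams()
    frames_a = six_frame_translate(a)
    frames_b = six_frame_translate(b)
    index = WordIndex([encode_aa(frames_b[f]) for f in FRAME_ORDER], word_size)
    total_b = index.total_residues
    la = len(a.seq)
    hsps: list[GenomeHsp] = []
    for f in FRAME_ORDER:
        qenc = encode_aa(frames_a[f])
        rows = ungapped_hsps_vs_index(qenc, index, params.xdrop, min_raw)
        m_aa = len(qenc)
        for sid, qs, qe, ss, se, raw, nid, mm in rows:
            ev = _evalue(int(raw), m_aa, total_b, 6, gapped=False)
            if ev > params.evalue_max:
                continue
            k = abs(f)
            lo = (k - 1) + 3 * int(qs)
            hi = (k - 1) + 3 * int(qe)
            if f < 0:
                lo, hi = la - hi, la - lo
            hsps.append(
                GenomeHsp(
                    f, FRAME_ORDER[int(sid)], int(qs), int(qe), int(ss), int(se),
                    lo, hi, int(raw), int(nid), _bitscore(int(raw), gapped=False), ev,
                )
            )
    return hsps


# ---------------------------------------------------------------------------
# nucleotide k-mismatch scanning
# ---------------------------------------------------------------------------

def scan_with_mismatches(
    pattern: str, subject: SequenceRecord, max_mm: int
) -> list[tuple[int, str, int]]:
    """Every ungapped occurrence of ``pattern`` on either strand of
    ``subject`` with Hamming distance <= ``max_mm``.

    Positions are 1-based starts of the matched segment on the forward
    strand; circular subjects are scanned across the origin. N matches
    nothing (counts as a mismatch on either side).
    """
    pattern = pattern.upper().replace("U", "T")
    if set(pattern) - set("ACGTN"):
        raise FormatError(
            f"pattern contains non-ACGTN characters: {sorted(set(pattern) - set('ACGTN'))}"
        )
    plen = len(pattern)
    if plen < 15:
        raise ParameterError("pattern must be >= 15 nt")
    if max_mm > plen / 4:
        raise ParameterError("max_mm must be <= len(pattern)/4")
    parr = encode_nt(pattern)
    sarr = encode_nt(subject.seq)
    L = len(sarr)
    ext = np.concatenate([sarr, sarr[: plen - 1]]) if subject.topology == "circular" else sarr
    matches: list[tuple[int, str, int]] = []
    for strand, pat in (("+", parr), ("-", revcomp_enc(parr))):
        npos = len(ext) - plen + 1
        if npos <= 0:
            continue
        mm = np.zeros(npos, dtype=np.int32)
        for k in range(plen):
            col = ext[k : k + npos]
            mm += ((col != pat[k]) | (col == 4) | (pat[k] == 4)).astype(np.int32)
        for i in np.nonzero(mm <= max_mm)[0]:
            if i < L:  # wrap duplicates start at >= L
                matches.append((int(i) + 1, strand, int(mm[i])))
    matches.sort(key=lambda t: (t[0], t[1]))
    return matches


# ---------------------------------------------------------------------------
# 12-column tabular hit files
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.3f}\t"
                f"{h.aln_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"expected 12 tab-separated columns, got {len(parts)}", line=lineno
                )
            try:
                hits.append(
                    AlignmentHit(
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"unparseable field: {exc}", line=lineno) from None
    return hits
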