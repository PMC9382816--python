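"""CRISPR repeat-spacer arrays and spacer-to-phage protospacer matching.

The scientific step this module exists for is the spacer -> phage
matching (evidence of past infection and therefore of the host range
of a phage found in a metagenome). Array *detection* is an
intentionally simplified consensus-repeat finder — maximal runs of
near-identical direct repeats with spacer-sized gaps — not a
re-implementation of the published CRISPR annotation tools; spacers
can always be supplied directly as FASTA to bypass it.

Matching is ungapped, both strands, with a small mismatch allowance
(default 2, which covers the exact and single-mismatch protospacers
reported in this system). Spacer and protospacer coordinates are
1-based inclusive on the forward strand of their respective genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .homology import scan_with_mismatches
from .seqio import SequenceRecord, decode_nt, encode_nt

DEFAULT_REPEAT_LEN = (23, 55)
DEFAULT_SPACER_LEN = (20, 60)
_WORD = 16  # anchor word length for repeat discovery


@dataclass
class CrisprArray:
    """An ordered repeat-spacer structure on a host genome.

    ``repeats`` has exactly one more element than ``spacers``; spacer
    entries are (index starting at 1, sequence, start, end) with
    1-based inclusive host coordinates.
    """

    host_id: str
    start: int
    end: int
    repeats: list[str]
    spacers: list[tuple[int, str, int, int]]

    def __post_init__(self):
        if len(self.repeats) != len(self.spacers) + 1:
            raise ContractError("#repeats must equal #spacers + 1")
        last_end = 0
        for idx, _seq, s, e in self.spacers:
            if s <= last_end or e < s:
                raise ContractError("spacers must be ordered and non-overlapping")
            last_end = e

    def spacer_seqs(self) -> list[tuple[int, str]]:
        return [(i, s) for i, s, _a, _b in self.spacers]


@dataclass
class ProtospacerMatch:
    """A spacer occurrence in a phage genome."""

    spacer_index: int
    phage_id: str
    position: int  # 1-based forward-strand start
    strand: str
    matched_length: int
    mismatch_count: int


def detect_arrays(
    genome: SequenceRecord,
    repeat_len: tuple[int, int] = DEFAULT_REPEAT_LEN,
    spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
    min_units: int = 3,
) -> list[CrisprArray]:
    """Find maximal runs of >= ``min_units`` near-identical direct
    repeats (each copy within 1 mismatch of the run consensus) whose
    gaps fall in the spacer length band.

    Anchoring is by exact shared 16-mers with consistent spacing, then
    repeat boundaries are grown while every copy stays within its
    mismatch budget. Overlapping candidates are resolved longest first.
    Returns an empty list when nothing qualifies.
    """
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    if rmin < _WORD:
        rmin = _WORD  # anchors cannot be shorter than the word
    arr = encode_nt(genome.seq)
    n = len(arr)
    if n < min_units * (rmin + smin):
        return []
    words: dict[bytes, list[int]] = {}
    view = arr.tobytes()
    for i in range(n - _WORD + 1):
        w = view[i : i + _WORD]
        if w in words:
            words[w].append(i)
        else:
            words[w] = [i]
    lo_gap, hi_gap = rmin + smin, rmax + smax
    candidates = []
    for w, pos in words.items():
        if len(pos) < min_units:
            continue
        run = [pos[0]]
        for p in pos[1:] + [None]:
            if p is not None and lo_gap <= p - run[-1] <= hi_gap:
                run.append(p)
            else:
                if len(run) >= min_units:
                    cand = _expand_run(arr, run, rmin, rmax, smin, smax)
                    if cand is not None:
                        candidates.append(cand)
                run = [p] if p is not None else []
    # longest-array-first overlap resolution
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    accepted: list[tuple[int, int, list[int], int]] = []
    for cand in candidates:
        s, e = cand[0], cand[1]
        if all(e <= a or s >= b for a, b, *_ in accepted):
            accepted.append(cand)
    arrays = []
    for s, e, starts, rep_len in sorted(accepted):
        repeats = [decode_nt(arr[p : p + rep_len]) for p in starts]
        spacers = []
        for i in range(len(starts) - 1):
            a = starts[i] + rep_len
            b = starts[i + 1]
            spacers.append((i + 1, decode_nt(arr[a:b]), a + 1, b))
        arrays.append(CrisprArray(genome.id, s + 1, e, repeats, spacers))
    return arrays


def _expand_run(arr, anchors, rmin, rmax, smin, smax):
    """Grow the shared-word anchors of one candidate run into full
    repeat copies; returns (start, end, repeat_starts, repeat_len) or
    None if the result violates the repeat/spacer bands."""
    anchors = list(anchors)
    k = len(anchors)
    budgets = np.zeros(k, dtype=int)
    min_period = min(b - a for a, b in zip(anchors, anchors[1:]))
    left = 0
    right = 0

    def column_ok(offsets):
        col = arr[offsets]
        vals, cnt = np.unique(col, return_counts=True)
        consensus = vals[np.argmax(cnt)]
        mism = col != consensus
        # a genuine repeat column is consensus-dominated; a random
        # column just outside the boundary is not
        if mism.sum() > max(1, k // 4):
            return None
        trial = budgets + mism
        if (trial > 1).any():
            return None
        return trial

    while _WORD + left + right < rmax and left + 1 + _WORD + right <= min_period - smin:
        if anchors[0] - left - 1 < 0:
            break
        trial = column_ok(np.array([a - left - 1 for a in anchors]))
        if trial is None:
            break
        budgets = trial
        left += 1
    while _WORD + left + right < rmax and left + _WORD + right + 1 <= min_period - smin:
        if anchors[-1] + _WORD + right >= len(arr):
            break
        trial = column_ok(np.array([a + _WORD + right for a in anchors]))
        if trial is None:
            break
        budgets = trial
        right += 1
    rep_len = _WORD + left + right
    if not rmin <= rep_len <= rmax:
        return None
    starts = [a - left for a in anchors]
    for a, b in zip(starts, starts[1:]):
        gap = b - (a + rep_len)
        if not smin <= gap <= smax:
            return None
    return starts[0], starts[-1] + rep_len, starts, rep_len


def _normalize_spacers(
    spacers: CrisprArray | Sequence,
) -> list[tuple[int, str]]:
    if isinstance(spacers, CrisprArray):
        return spacers.spacer_seqs()
    out = []
    for i, sp in enumerate(spacers, 1):
        if isinstance(sp, SequenceRecord):
            out.append((i, sp.seq))
        elif isinstance(sp, tuple):
            out.append((int(sp[0]), str(sp[1])))
        else:
            out.append((i, str(sp)))
    return out


def match_spacers(
    spacers: CrisprArray | Sequence,
    phage: SequenceRecord,
    max_mm: int = 2,
) -> list[ProtospacerMatch]:
    """All ungapped occurrences of each spacer in a phage genome on
    either strand with <= ``max_mm`` mismatches, sorted by spacer index
    then position. Accepts a detected array, SequenceRecords, plain
    strings, or (index, sequence) tuples."""
    matches: list[ProtospacerMatch] = []
    for idx, seq in _normalize_spacers(spacers):
        for pos, strand, mm in scan_with_mismatches(seq, phage, max_mm):
            matches.append(
                ProtospacerMatch(idx, phage.id, pos, strand, len(seq), mm)
            )
    matches.sort(key=lambda m: (m.spacer_index, m.position, m.strand))
    return matches


def spacer_report(
    arrays: CrisprArray | list[CrisprArray],
    matches: Iterable[ProtospacerMatch],
    phage_ids: Sequence[str],
) -> pd.DataFrame:
    """One row per (spacer, phage): match status, best position/strand/
    mismatches (fewest mismatches, then leftmost), and the number of
    occurrences. Spacers with no match are flagged ``unmatched``."""
    if isinstance(arrays, CrisprArray):
        arrays = [arrays]
    by_key: dict[tuple[int, str], list[ProtospacerMatch]] = {}
    for m in matches:
        by_key.setdefault((m.spacer_index, m.phage_id), []).append(m)
    rows = []
    for arr in arrays:
        for idx, seq in arr.spacer_seqs():
            for pid in phage_ids:
                ms = sorted(
                    by_key.get((idx, pid), []),
                    key=lambda m: (m.mismatch_count, m.position),
                )
                if ms:
                    best = ms[0]
                    rows.append(
                        (arr.host_id, idx, len(seq), pid, "matched",
                         best.position, best.strand, best.mismatch_count, len(ms))
                    )
                else:
                    rows.append(
                        (arr.host_id, idx, len(seq), pid, "unmatched",
                         pd.NA, pd.NA, pd.NA, 0)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "host_id", "spacer_index", "spacer_length", "phage_id", "status",
            "position", "strand", "mismatches", "n_occurrences",
        ],
    )
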