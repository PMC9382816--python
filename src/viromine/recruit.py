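"""Reciprocal best-hit (RBB) recruitment of metagenomic reads to
reference phage genomes, and genome-length-normalized abundance.

The two-pass strategy:

* **Forward pass** — every reference protein is searched against the
  read set (protein vs translated DNA, E-value <= 1e-3); the union of
  hit reads per phage forms the candidate set.
* **Reciprocal pass** — each candidate read is searched (DNA vs
  protein, single best target) against the combined database of
  reference proteomes plus a decoy proteome of unrelated tailed
  phages. A read is assigned to phage *i* iff its single best
  reciprocal hit is a protein of phage *i*; a best hit in a decoy
  leaves it unassigned, and a bitscore tie spanning a decoy and a
  reference, or two different references, makes it ambiguous.

Reads are counted per read, not per HSP: a read hitting several
proteins of the same phage counts once. Relative abundance is read
count normalized by genome length:

    fraction_i = (n_i / L_i) / sum_j (n_j / L_j)

Ambiguous ties are excluded from abundance by default
(``tie_policy="drop"``); ``"split"`` shares such reads equally among
the tied reference phages instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from ._scoring import bitscore as _bitscore, encode_aa, evalue as _evalue
from .errors import ParameterError, UndefinedValueError
from .homology import (
    AlignmentHit,
    BatchHit,
    SearchParams,
    WordIndex,
    batch_search_reads,
)
from .seqio import SequenceRecord, frame_to_forward

Status = Literal["assigned", "unassigned", "ambiguous"]

# Exact-word seed length of the batch recruitment path. Longer than the
# per-query default (3) for index selectivity at recruitment scale;
# high-identity read recruitment loses no sensitivity from it.
RECRUIT_WORD_SIZE = 4


@dataclass
class ReferencePhage:
    """One reference phage: genome, proteome, and (when known) each
    protein's genome location, used for coverage maps."""

    phage_id: str
    genome: SequenceRecord
    proteins: list[SequenceRecord]
    protein_locs: dict[str, tuple[int, int, str]] | None = None

    def __post_init__(self):
        if len(self.genome.seq) <= 0:
            raise ParameterError("genome length must be positive")


@dataclass
class ReferenceSet:
    """The reference panel the reads are recruited against."""

    phages: list[ReferencePhage]

    def __post_init__(self):
        ids = [p.phage_id for p in self.phages]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate phage ids in reference set")
        pids = [pr.id for ph in self.phages for pr in ph.proteins]
        if len(set(pids)) != len(pids):
            raise ParameterError("a protein id maps to more than one phage")

    @property
    def genomes(self) -> dict[str, SequenceRecord]:
        return {p.phage_id: p.genome for p in self.phages}

    def genome_length(self, phage_id: str) -> int:
        return len(self.genomes[phage_id].seq)

    def tagged_proteins(self) -> list[tuple[SequenceRecord, str]]:
        return [(pr, ph.phage_id) for ph in self.phages for pr in ph.proteins]

    def protein_location(self, protein_id: str):
        for ph in self.phages:
            if ph.protein_locs and protein_id in ph.protein_locs:
                return ph.protein_locs[protein_id]
        return None


@dataclass
class ReadAssignment:
    read_id: str
    status: Status
    phage: str | None = None
    forward_hit: AlignmentHit | None = None
    reciprocal_hit: AlignmentHit | None = None
    tied: tuple[str, ...] = ()


@dataclass
class RecruitmentResult:
    assignments: list[ReadAssignment]
    reference_ids: list[str]

    @property
    def counts(self) -> dict[str, int]:
        c = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
        for a in self.assignments:
            c[a.status] += 1
        return c

    def assigned_counts(self) -> dict[str, int]:
        c = {pid: 0 for pid in self.reference_ids}
        for a in self.assignments:
            if a.status == "assigned":
                c[a.phage] += 1
        return c

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            f, r = a.forward_hit, a.reciprocal_hit
            rows.append(
                (
                    a.read_id, a.status, a.phage or "",
                    f.query_id if f else "", f.bitscore if f else np.nan,
                    r.subject_id if r else "", r.bitscore if r else np.nan,
                    r.percent_identity if r else np.nan, ";".join(a.tied),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "read_id", "status", "phage", "forward_protein", "forward_bitscore",
                "reciprocal_protein", "reciprocal_bitscore",
                "reciprocal_identity_pct", "tied",
            ],
        )


def _forward_hit(
    bh: BatchHit, prot: SequenceRecord, read: SequenceRecord,
    total_read_aa: int, n_read_frames: int, params: SearchParams,
) -> AlignmentHit:
    """Express a read-frame HSP in the forward orientation (protein
    query, read subject), tblastn-style."""
    s_start, s_end = frame_to_forward(bh.frame, bh.q_aa_start, bh.q_aa_end, len(read.seq))
    ev = _evalue(bh.raw, len(prot.seq), total_read_aa, n_read_frames, gapped=False)
    return AlignmentHit(
        prot.id, read.id, 100.0 * bh.nident / bh.aln_length, bh.aln_length,
        bh.mismatches, 0, bh.s_start + 1, bh.s_end, s_start, s_end,
        ev, bh.bitscore, frame=bh.frame, raw_score=bh.raw,
    )


def _reciprocal_hit(bh: BatchHit, read: SequenceRecord, prot: SequenceRecord) -> AlignmentHit:
    """Express a read-frame HSP in the reciprocal orientation (read
    query, protein subject), blastx-style."""
    q_start, q_end = frame_to_forward(bh.frame, bh.q_aa_start, bh.q_aa_end, len(read.seq))
    return AlignmentHit(
        read.id, prot.id, 100.0 * bh.nident / bh.aln_length, bh.aln_length,
        bh.mismatches, 0, q_start, q_end, bh.s_start + 1, bh.s_end,
        bh.evalue, bh.bitscore, frame=bh.frame, raw_score=bh.raw,
    )


def recruit_reads(
    reads: Iterable[SequenceRecord],
    refs: ReferenceSet,
    decoys: list[SequenceRecord],
    params: SearchParams | None = None,
) -> RecruitmentResult:
    """Two-pass reciprocal best-hit recruitment of reads to reference
    phages. See the module docstring for the assignment rules."""
    params = params or SearchParams(word_size=RECRUIT_WORD_SIZE, max_targets=1)
    reads = list(reads)
    ref_tagged = refs.tagged_proteins()
    if not ref_tagged:
        raise ParameterError("reference set has an empty proteome")
    if not decoys:
        warnings.warn(
            "empty decoy set: the reciprocal stage degenerates to "
            "self-confirmation and cannot reject non-reference reads",
            stacklevel=2,
        )
    ref_ids = [p.phage_id for p in refs.phages]
    if not reads:
        return RecruitmentResult([], ref_ids)

    total_read_aa = sum(2 * (len(r.seq) - k) // 3 for r in reads for k in (0, 1, 2))
    n_read_frames = 6 * len(reads)

    # forward pass: reads against the reference proteome
    ref_prots = [t[0] for t in ref_tagged]
    fwd_index = WordIndex([encode_aa(p.seq) for p in ref_prots], params.word_size)
    fwd_hits = batch_search_reads(reads, fwd_index, params)

    candidates = [i for i, hits in enumerate(fwd_hits) if hits]

    # reciprocal pass: candidates against reference + decoy proteins
    combined = ref_prots + list(decoys)
    tags: list[str | None] = [t[1] for t in ref_tagged] + [None] * len(decoys)
    rec_index = WordIndex([encode_aa(p.seq) for p in combined], params.word_size)
    rec_hits = batch_search_reads((reads[i] for i in candidates), rec_index, params)

    prot_phage = {i: tag for i, tag in enumerate(tags)}
    assignments: dict[int, ReadAssignment] = {}
    for ci, hits in zip(candidates, rec_hits):
        read = reads[ci]
        if not hits:
            assignments[ci] = ReadAssignment(read.id, "unassigned")
            continue
        max_raw = max(h.raw for h in hits)
        tied = sorted(
            (h for h in hits if h.raw == max_raw),
            key=lambda h: combined[h.prot].id,
        )
        tied_tags = {prot_phage[h.prot] for h in tied}
        tag_names = tuple(sorted("decoy" if t is None else t for t in tied_tags))
        best = tied[0]
        rec_hit = _reciprocal_hit(best, read, combined[best.prot])
        if len(tied_tags) > 1:
            assignments[ci] = ReadAssignment(
                read.id, "ambiguous", None, None, rec_hit, tag_names
            )
            continue
        tag = next(iter(tied_tags))
        if tag is None:
            assignments[ci] = ReadAssignment(read.id, "unassigned", None, None, rec_hit)
            continue
        # forward hit of the assigned phage (fall back to overall best)
        own = [h for h in fwd_hits[ci] if ref_tagged[h.prot][1] == tag]
        pool = own or fwd_hits[ci]
        fb = max(pool, key=lambda h: (h.raw, -h.prot))
        fwd = _forward_hit(fb, ref_prots[fb.prot], read, total_read_aa, n_read_frames, params)
        assignments[ci] = ReadAssignment(read.id, "assigned", tag, fwd, rec_hit)

    final = [
        assignments.get(i, ReadAssignment(reads[i].id, "unassigned"))
        for i in range(len(reads))
    ]
    return RecruitmentResult(final, ref_ids)


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Per-phage read counts and genome-length-normalized abundance.

    ``table`` columns: phage, read_count, genome_length, density
    (reads per bp), relative_fraction (sums to 1), percent (1 decimal).
    """

    table: pd.DataFrame

    def fractions(self) -> dict[str, float]:
        return dict(zip(self.table["phage"], self.table["relative_fraction"]))

    def percents(self) -> dict[str, float]:
        return dict(zip(self.table["phage"], self.table["percent"]))


def compute_abundance(
    result: RecruitmentResult,
    refs: ReferenceSet,
    tie_policy: Literal["drop", "split"] = "drop",
) -> AbundanceTable:
    """Genome-length-normalized relative abundance from a recruitment.

    ``fraction_i = (n_i/L_i) / sum_j (n_j/L_j)``. Under
    ``tie_policy="split"``, ambiguous reads tied exclusively among
    reference phages contribute 1/k to each; ties involving a decoy
    are always dropped.
    """
    counts: dict[str, float] = {p.phage_id: 0.0 for p in refs.phages}
    for a in result.assignments:
        if a.status == "assigned":
            counts[a.phage] += 1.0
        elif a.status == "ambiguous" and tie_policy == "split":
            members = [t for t in a.tied if t in counts]
            if members and len(members) == len(a.tied):
                for t in members:
                    counts[t] += 1.0 / len(members)
    if all(v == 0 for v in counts.values()):
        raise UndefinedValueError("no reads assigned: abundance fractions undefined")
    rows = []
    dens = {pid: counts[pid] / refs.genome_length(pid) for pid in counts}
    total = sum(dens.values())
    for pid in counts:
        frac = dens[pid] / total
        rows.append(
            (pid, counts[pid], refs.genome_length(pid), dens[pid], frac,
             round(100.0 * frac, 1))
        )
    return AbundanceTable(
        pd.DataFrame(
            rows,
            columns=[
                "phage", "read_count", "genome_length", "density",
                "relative_fraction", "percent",
            ],
        )
    )


def coverage_map(
    result: RecruitmentResult,
    refs: ReferenceSet,
    identity_floor: float = 30.0,
) -> dict[str, list[tuple[int, int, float]]]:
    """Identity-vs-position track per phage from assigned reads.

    Each assigned read contributes the genome interval its forward-hit
    protein region maps to, with the hit's percent identity clipped to
    the [identity_floor, 100] display band. Intervals are 0-based
    half-open, sorted by start. Phages with no assigned reads get an
    empty track. Reads whose forward-hit protein has no recorded
    genome location are skipped.
    """
    tracks: dict[str, list[tuple[int, int, float]]] = {
        p.phage_id: [] for p in refs.phages
    }
    for a in result.assignments:
        if a.status != "assigned" or a.forward_hit is None:
            continue
        loc = refs.protein_location(a.forward_hit.query_id)
        if loc is None:
            continue
        s, e, strand = loc
        q0, q1 = a.forward_hit.q_start - 1, a.forward_hit.q_end  # aa, half-open
        if strand == "+":
            lo, hi = s + 3 * q0, s + 3 * q1
        else:
            lo, hi = e - 3 * q1, e - 3 * q0
        ident = min(100.0, max(identity_floor, a.forward_hit.percent_identity))
        tracks[a.phage].append((lo, hi, ident))
    for pid in tracks:
        tracks[pid].sort()
    return tracks
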