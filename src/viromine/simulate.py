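"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: circular phage
genomes with planted ORFs and their proteomes, metagenomic read sets
drawn at spiked relative abundances with substitution errors, decoy
genomes/proteins, contigs carrying terminal direct repeats, and host
genomes carrying a planted CRISPR repeat-spacer array whose spacers
derive from a donor phage.

The default community mirrors the study conditions this package was
built around: five phages with genome lengths 36,043 / 142,856 /
54,544 / 48,349 / 39,509 bp at relative abundances 48.7 / 8.9 / 3.1 /
5.2 / 34.1 %, 50,000 reads of 150 nt with a 1% substitution error
rate, plus a 20% decoy read fraction drawn from unrelated phage
genomes.

Reads are drawn with per-phage weights proportional to
abundance * genome_length, so the genome-length-normalized abundance
estimator is unbiased for the spiked abundance vector ("relative
abundance" here means genome-copy fraction, not read fraction). The
error model is substitution-only.

All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mine import ContigRecord
from .seqio import (
    DEFAULT_TRANSLATION_TABLE,
    OrfCall,
    SequenceRecord,
    _codon_table,
    decode_nt,
    encode_nt,
    naive_orf_scan,
    revcomp_enc,
    translate_enc,
)

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Namespaced deterministic generator: distinct spawn keys give
    provably independent streams even for related seeds (plain
    ``default_rng([a, b])`` zero-pads, so e.g. seeds 3 and [3, 0]
    collide)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# community specification
# ---------------------------------------------------------------------------

@dataclass
class PhageSpec:
    id: str
    genome_length: int
    gc: float
    relative_abundance: float


@dataclass
class CommunitySpec:
    """A spiked phage community: who is present, at what abundance, and
    how it was sequenced."""

    phages: list[PhageSpec]
    n_reads: int = 50_000
    read_length: int = 150
    substitution_error_rate: float = 0.01
    decoy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        total = sum(p.relative_abundance for p in self.phages)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"relative abundances must sum to 1 (got {total})")
        if not 0 <= self.substitution_error_rate <= 0.1:
            raise ParameterError("substitution_error_rate must be in [0, 0.1]")
        if not 0 <= self.decoy_fraction < 1:
            raise ParameterError("decoy_fraction must be in [0, 1)")


def default_community_spec(seed: int = 0, n_reads: int = 50_000) -> CommunitySpec:
    """The five-phage community at the study's genome lengths and
    spiked abundances (48.7/8.9/3.1/5.2/34.1 % for pam1..pam5); G+C is
    35% except for the high-GC pam4 at 73.6%."""
    return CommunitySpec(
        phages=[
            PhageSpec("pam1", 36_043, 0.35, 0.487),
            PhageSpec("pam2", 142_856, 0.35, 0.089),
            PhageSpec("pam3", 54_544, 0.35, 0.031),
            PhageSpec("pam4", 48_349, 0.736, 0.052),
            PhageSpec("pam5", 39_509, 0.35, 0.341),
        ],
        n_reads=n_reads,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genome generator
# ---------------------------------------------------------------------------

class SyntheticGenome(NamedTuple):
    genome: SequenceRecord
    proteins: list[SequenceRecord]
    protein_locs: dict[str, tuple[int, int, str]]
    orfs: list[OrfCall]


def _sample_bases(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _sample_codons(rng, n: int, gc: float) -> np.ndarray:
    """n stop-free codons as a flat encoded array, base composition at
    the target GC."""
    out = np.empty((n, 3), np.uint8)
    todo = np.arange(n)
    stop_codes = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA
    while len(todo):
        cand = _sample_bases(rng, len(todo) * 3, gc).reshape(-1, 3)
        bad = np.array([tuple(row) in stop_codes for row in map(tuple, cand)])
        out[todo[~bad]] = cand[~bad]
        todo = todo[bad]
    return out.reshape(-1)


def _syn_codons(aa: str, table_id: int = DEFAULT_TRANSLATION_TABLE) -> list[np.ndarray]:
    table = _codon_table(table_id)
    return [
        np.array([c >> 4, (c >> 2) & 3, c & 3], np.uint8)
        for c in range(64)
        if chr(table[c]) == aa
    ]


def make_genome(
    length: int,
    gc: float,
    n_genes: int,
    seed: int,
    gene_len_range: tuple[int, int] = (100, 400),
    min_gap: int = 10,
    orf_guard_min_aa: int = 100,
    genome_id: str = "synthetic",
    coding_nt: int | None = None,
) -> SyntheticGenome:
    """A circular genome with ``n_genes`` planted non-overlapping ORFs
    (ATG..stop, stop-free interiors) on both strands, and its proteome.

    The backbone is random at the target GC (held within +/- 0.01 by
    flipping intergenic bases when needed). A stop codon is planted
    immediately upstream of each ORF in its own frame so the planted
    ATG starts a *maximal* ORF, and any unplanned maximal ORF of
    >= ``orf_guard_min_aa`` aa is disrupted by a synonymous (inside
    genes) or direct (intergenic) stop-codon edit, so a naive ORF scan
    at that threshold recovers exactly the planted genes.
    """
    if length < 5_000:
        raise ParameterError("genome length must be >= 5,000")
    if not 0.2 <= gc <= 0.8:
        raise ParameterError("gc must be in [0.2, 0.8]")
    lo, hi = gene_len_range
    if lo < 10 or hi < lo:
        raise ParameterError("bad gene_len_range")
    for attempt in range(12):
        rng = _rng(seed, 1, attempt)
        aa_lens = rng.integers(lo, hi + 1, n_genes)
        if coding_nt is not None:
            # pin total ORF length exactly (comparable coding fraction
            # across genomes of a community)
            target_aa = coding_nt // 3 - n_genes
            if not n_genes * lo <= target_aa <= n_genes * hi:
                raise ParameterError("coding_nt infeasible for gene_len_range")
            diff = int(target_aa - aa_lens.sum())
            guard_iter = 0
            while diff != 0 and guard_iter < 100_000:
                g = int(rng.integers(n_genes))
                step = 1 if diff > 0 else -1
                if lo <= aa_lens[g] + step <= hi:
                    aa_lens[g] += step
                    diff -= step
                guard_iter += 1
        blocks = 3 + 3 * (aa_lens + 1)  # guard stop + ATG..stop
        overhead = int(blocks.sum()) + min_gap * (n_genes + 1)
        if overhead > length:
            raise ParameterError(
                f"{n_genes} genes of {lo}-{hi} aa do not fit in {length} bp"
            )
        extra = rng.multinomial(length - overhead, np.full(n_genes + 1, 1 / (n_genes + 1)))
        strands = rng.integers(0, 2, n_genes)
        arr = _sample_bases(rng, length, gc)
        pos = 0
        genes: list[tuple[int, int, str]] = []  # ORF start, end, strand (fwd coords)
        guards: list[tuple[int, int]] = []
        for g in range(n_genes):
            pos += min_gap + int(extra[g])
            aa_n = int(aa_lens[g])
            orf = np.empty(3 * (aa_n + 1), np.uint8)
            orf[0:3] = (0, 3, 2)  # ATG
            orf[3 : 3 * aa_n] = _sample_codons(rng, aa_n - 1, gc)
            orf[3 * aa_n :] = encode_nt(_STOP_CODONS[rng.integers(3)])
            guard = encode_nt(_STOP_CODONS[rng.integers(3)])
            if strands[g] == 0:
                arr[pos : pos + 3] = guard
                s = pos + 3
                arr[s : s + len(orf)] = orf
                genes.append((s, s + len(orf), "+"))
                guards.append((pos, pos + 3))
            else:
                s = pos
                arr[s : s + len(orf)] = revcomp_enc(orf)
                arr[s + len(orf) : s + len(orf) + 3] = revcomp_enc(guard)
                genes.append((s, s + len(orf), "-"))
                guards.append((s + len(orf), s + len(orf) + 3))
            pos += int(blocks[g])
        arr = _tune_gc(rng, arr, gc, genes, guards)
        arr, ok = _suppress_spurious_orfs(rng, arr, genes, guards, orf_guard_min_aa)
        if not ok:
            continue
        genome = SequenceRecord(genome_id, decode_nt(arr), topology="circular")
        proteins: list[SequenceRecord] = []
        locs: dict[str, tuple[int, int, str]] = {}
        orfs: list[OrfCall] = []
        for i, (s, e, strand) in enumerate(genes, 1):
            sub = arr[s:e] if strand == "+" else revcomp_enc(arr[s:e])
            prot = translate_enc(sub)[:-1]  # drop the stop
            pid = f"{genome_id}_p{i:03d}"
            proteins.append(SequenceRecord(pid, prot, description=f"{genome_id}:{s}-{e}({strand})"))
            locs[pid] = (s, e, strand)
            frame = (s % 3) + 1 if strand == "+" else ((len(arr) - e) % 3) + 4
            orfs.append(OrfCall(s, e, strand, frame, prot))
        return SyntheticGenome(genome, proteins, locs, orfs)
    raise ParameterError(
        "could not build a genome free of unplanned long ORFs; "
        "lower orf_guard_min_aa or gene density"
    )


def _tune_gc(rng, arr, gc, genes, guards):
    """Flip intergenic A/T<->G/C bases until |GC - target| <= 0.01."""
    counts = np.bincount(arr, minlength=5)
    gc_now = (counts[1] + counts[2]) / len(arr)
    delta = int(round((gc - gc_now) * len(arr)))
    if abs(gc - gc_now) <= 0.01:
        return arr
    free = np.ones(len(arr), bool)
    for s, e in [(g[0], g[1]) for g in genes] + guards:
        free[s:e] = False
    # A->G, T->C raises GC; G->A, C->T lowers it
    if delta > 0:
        cand = np.nonzero(free & ((arr == 0) | (arr == 3)))[0]
    else:
        cand = np.nonzero(free & ((arr == 1) | (arr == 2)))[0]
    take = min(abs(delta), len(cand))
    pick = rng.choice(cand, size=take, replace=False)
    arr = arr.copy()
    if delta > 0:
        arr[pick] = np.where(arr[pick] == 0, 2, 1)
    else:
        arr[pick] = np.where(arr[pick] == 2, 0, 3)
    return arr


def _orf_codon_window(call: OrfCall, j: int) -> tuple[int, int]:
    """Forward-strand interval of codon ``j`` of an ORF (counting from
    its ATG)."""
    if call.strand == "+":
        s = call.start + 3 * j
    else:
        s = call.end - 3 * (j + 1)
    return s, s + 3


def _suppress_spurious_orfs(rng, arr, genes, guards, min_aa):
    """Disrupt every unplanned maximal ORF >= min_aa by planting a stop
    codon in its frame near its middle: directly when the site is
    intergenic, via a synonymous gene-codon substitution when it falls
    inside a planted gene. Returns (array, success)."""
    planted = {(s, e, st) for s, e, st in genes}
    blocked = np.zeros(len(arr), bool)
    for s, e in guards:
        blocked[s:e] = True
    gene_at = np.full(len(arr), -1, np.int64)
    for gi, (s, e, _st) in enumerate(genes):
        gene_at[s:e] = gi
    for _round in range(15):
        rec = SequenceRecord("tmp", decode_nt(arr))
        extras = [
            c
            for c in naive_orf_scan(rec, min_aa)
            if (c.start, c.end, c.strand) not in planted
        ]
        if not extras:
            return arr, True
        progress = False
        for call in extras:
            n_codons = (call.end - call.start) // 3
            mid = n_codons // 2
            # try codon sites spiralling out from the middle
            order = sorted(range(1, n_codons - 1), key=lambda j: abs(j - mid))
            done = False
            for j in order:
                w0, w1 = _orf_codon_window(call, j)
                gi = int(gene_at[w0])
                if gene_at[w0] != gene_at[w1 - 1] or blocked[w0:w1].any():
                    continue
                if gi < 0:
                    stop = encode_nt(_STOP_CODONS[rng.integers(3)])
                    arr[w0:w1] = stop if call.strand == "+" else revcomp_enc(stop)
                    done = True
                    break
                if _synonymous_stop_edit(arr, genes[gi], call, w0):
                    done = True
                    break
            progress = progress or done
        if not progress:
            return arr, False
    return arr, False


def _synonymous_stop_edit(arr, gene, call, w0) -> bool:
    """Try to replace the gene codon covering ``w0`` (or a neighbour)
    by a synonymous codon that creates a stop in ``call``'s frame."""
    gs, ge, gstrand = gene
    # gene codon indices overlapping the 3-nt window starting at w0
    if gstrand == "+":
        ks = {(w0 - gs) // 3, (w0 + 2 - gs) // 3}
    else:
        ks = {(ge - 1 - w0) // 3, (ge - 3 - w0) // 3}
    n_codons = (ge - gs) // 3
    for k in sorted(ks):
        if not 1 <= k < n_codons - 1:  # never touch ATG or the stop
            continue
        if gstrand == "+":
            c0 = gs + 3 * k
            cur = arr[c0 : c0 + 3].copy()
            aa = translate_enc(cur)
        else:
            c0 = ge - 3 * (k + 1)
            cur = arr[c0 : c0 + 3].copy()
            aa = translate_enc(revcomp_enc(cur))
        for syn in _syn_codons(aa):
            cand = syn if gstrand == "+" else revcomp_enc(syn)
            if np.array_equal(cand, cur):
                continue
            arr[c0 : c0 + 3] = cand
            if _orf_interior_stop(arr, call):
                return True
        arr[c0 : c0 + 3] = cur
    return False


def _orf_interior_stop(arr, call) -> bool:
    """Does ``call``'s span now contain a stop before its terminal one?"""
    sub = arr[call.start : call.end]
    if call.strand == "-":
        sub = revcomp_enc(sub)
    aa = translate_enc(sub)
    return "*" in aa[:-1]


# ---------------------------------------------------------------------------
# read simulator
# ---------------------------------------------------------------------------

class ReadSet(NamedTuple):
    reads: list[SequenceRecord]
    truth: pd.DataFrame  # read_id, source, position, strand, n_errors


def make_reads(
    genomes: dict[str, SequenceRecord],
    spec: CommunitySpec,
    decoy_genomes: dict[str, SequenceRecord] | None = None,
) -> ReadSet:
    """Draw reads from a spiked community.

    Per-phage read counts are multinomial with weights
    abundance_i * L_i; start positions are uniform with circular
    wrap-around, strands uniform, substitutions i.i.d. at the spec'd
    rate. ``decoy_fraction`` of the reads come from the decoy genomes
    (weighted by length alone). Returns the reads plus a truth table.
    """
    rng = _rng(spec.seed, 2)
    rl = spec.read_length
    ids = [p.id for p in spec.phages]
    missing = [i for i in ids if i not in genomes]
    if missing:
        raise ParameterError(f"genomes missing for {missing}")
    if rl >= min(len(genomes[i].seq) for i in ids):
        raise ParameterError("read_length must be shorter than the smallest genome")
    decoy_genomes = decoy_genomes or {}
    n_decoy = int(round(spec.n_reads * spec.decoy_fraction)) if decoy_genomes else 0
    n_target = spec.n_reads - n_decoy
    w = np.array([p.relative_abundance * p.genome_length for p in spec.phages])
    counts = rng.multinomial(n_target, w / w.sum())
    sources = list(zip(ids, counts))
    if n_decoy:
        dids = sorted(decoy_genomes)
        dw = np.array([len(decoy_genomes[d].seq) for d in dids], float)
        dcounts = rng.multinomial(n_decoy, dw / dw.sum())
        sources += list(zip(dids, dcounts))
    all_genomes = {**genomes, **decoy_genomes}
    seqs: list[np.ndarray] = []
    rows = []
    for src, c in sources:
        if c == 0:
            continue
        arr = encode_nt(all_genomes[src].seq)
        doubled = np.concatenate([arr, arr[:rl]])
        starts = rng.integers(0, len(arr), c)
        strands = rng.integers(0, 2, c)
        block = doubled[starts[:, None] + np.arange(rl)[None, :]]
        rev = np.nonzero(strands)[0]
        block[rev] = 3 - block[rev, ::-1]  # revcomp (no N in synthetic genomes)
        err_mask = rng.random((c, rl)) < spec.substitution_error_rate
        n_err = err_mask.sum(axis=1)
        if err_mask.any():
            ei, ej = np.nonzero(err_mask)
            block[ei, ej] = (block[ei, ej] + rng.integers(1, 4, len(ei))) % 4
        for k in range(c):
            seqs.append(block[k])
            rows.append((src, int(starts[k]), "-" if strands[k] else "+", int(n_err[k])))
    perm = rng.permutation(len(seqs))
    reads = []
    truth_rows = []
    for new_i, old_i in enumerate(perm):
        rid = f"read_{new_i:06d}"
        reads.append(SequenceRecord(rid, decode_nt(seqs[old_i])))
        src, pos, strand, ne = rows[old_i]
        truth_rows.append((rid, src, pos, strand, ne))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source", "position", "strand", "n_errors"]
    )
    return ReadSet(reads, truth)


class Community(NamedTuple):
    """A fully generated study community: reference panel (genomes +
    proteomes with gene coordinates), decoy genomes/proteins, the read
    set and its truth table."""

    refs: "object"  # recruit.ReferenceSet (typed loosely to avoid a cycle in tools)
    decoy_genomes: dict[str, SequenceRecord]
    decoy_proteins: list[SequenceRecord]
    reads: list[SequenceRecord]
    truth: pd.DataFrame


def make_community(
    spec: CommunitySpec,
    genome_seed: int = 1000,
    coding_density: float = 0.7,
    n_decoy_genomes: int = 3,
    decoy_genome_length: int = 40_000,
    decoy_gc: float = 0.45,
) -> Community:
    """Generate the whole community experiment from a spec.

    Genomes are built with the same coding density (total ORF length
    pinned to ``coding_density * L``) so that the per-read recruitment
    probability is comparable across phages; ``genome_seed`` is
    independent of ``spec.seed`` so the same genomes can be resequenced
    under different read seeds.
    """
    from .recruit import ReferencePhage, ReferenceSet

    phages = []
    for i, ph in enumerate(spec.phages):
        cnt = int(coding_density * ph.genome_length)
        n_genes = max(1, round(cnt / 753))
        g = make_genome(
            ph.genome_length, ph.gc, n_genes, seed=genome_seed + i,
            coding_nt=cnt, genome_id=ph.id,
        )
        phages.append(ReferencePhage(ph.id, g.genome, g.proteins, g.protein_locs))
    refs = ReferenceSet(phages)
    decoy_genomes: dict[str, SequenceRecord] = {}
    decoy_proteins: list[SequenceRecord] = []
    for j in range(n_decoy_genomes):
        cnt = int(coding_density * decoy_genome_length)
        g = make_genome(
            decoy_genome_length, decoy_gc, max(1, round(cnt / 753)),
            seed=genome_seed + 10_000 + j, coding_nt=cnt, genome_id=f"decoy{j + 1}",
        )
        decoy_genomes[g.genome.id] = g.genome
        decoy_proteins.extend(g.proteins)
    reads, truth = make_reads(refs.genomes, spec, decoy_genomes or None)
    return Community(refs, decoy_genomes, decoy_proteins, reads, truth)


# ---------------------------------------------------------------------------
# contig and CRISPR fixtures
# ---------------------------------------------------------------------------

def make_circular_contig(genome: SequenceRecord, overlap_len: int) -> ContigRecord:
    """A contig built as the genome plus its first ``overlap_len`` bases
    re-appended (the terminal direct repeat an assembler leaves on a
    circular genome). ``overlap_len=0`` gives a plain linear contig."""
    if overlap_len < 0 or overlap_len > len(genome.seq):
        raise ParameterError("overlap_len must be in [0, genome length]")
    seq = genome.seq + genome.seq[:overlap_len]
    return ContigRecord(
        record=SequenceRecord(f"{genome.id}_contig", seq, topology="linear"),
    )


class CrisprHost(NamedTuple):
    host: SequenceRecord
    truth: pd.DataFrame  # spacer_index, start, end, from_donor, donor_pos, donor_strand, mismatches
    array_start: int  # 1-based
    array_end: int
    repeat: str
    spacers: list[str]


def make_crispr_host(
    donor_phage: SequenceRecord,
    host_length: int = 100_000,
    n_spacers: int = 13,
    repeat_len: int = 36,
    spacer_len: int = 35,
    protospacer_indices: tuple[int, ...] = (7, 9, 11, 12, 13),
    protospacer_mismatches: tuple[int, ...] = (0, 0, 0, 1, 0),
    gc: float = 0.5,
    seed: int = 0,
) -> CrisprHost:
    """A host genome carrying one planted CRISPR array: ``n_spacers``+1
    identical repeats interleaving ``n_spacers`` spacers, of which the
    listed indices are copied from the donor phage with the stated
    per-spacer mismatch counts (the default pattern mirrors four exact
    protospacers plus one with a single mismatch). Remaining spacers
    are random."""
    if len(protospacer_indices) != len(protospacer_mismatches):
        raise ParameterError("protospacer index/mismatch lists differ in length")
    if len(set(protospacer_indices)) != len(protospacer_indices):
        raise ParameterError("duplicate protospacer indices")
    if any(not 1 <= i <= n_spacers for i in protospacer_indices):
        raise ParameterError("protospacer indices out of range")
    rng = _rng(seed, 3)
    repeat = decode_nt(_sample_bases(rng, repeat_len, gc))
    donor = encode_nt(donor_phage.seq)
    mism = dict(zip(protospacer_indices, protospacer_mismatches))
    spacers: list[str] = []
    truth_rows = []
    used: list[tuple[int, int]] = []
    for idx in range(1, n_spacers + 1):
        if idx in mism:
            while True:
                p = int(rng.integers(0, len(donor) - spacer_len + 1))
                if all(p + spacer_len <= a or p >= b for a, b in used):
                    break
            used.append((p, p + spacer_len))
            strand = "+" if rng.integers(2) == 0 else "-"
            seg = donor[p : p + spacer_len].copy()
            if strand == "-":
                seg = revcomp_enc(seg)
            m = mism[idx]
            if m:
                sites = rng.choice(spacer_len, size=m, replace=False)
                seg[sites] = (seg[sites] + rng.integers(1, 4, m)) % 4
            spacers.append(decode_nt(seg))
            truth_rows.append((idx, True, p + 1, strand, m))
        else:
            spacers.append(decode_nt(_sample_bases(rng, spacer_len, gc)))
            truth_rows.append((idx, False, pd.NA, pd.NA, 0))
    array_seq = repeat + "".join(sp + repeat for sp in spacers)
    if len(array_seq) + 2000 > host_length:
        raise ParameterError("host_length too small for the array")
    backbone_len = host_length - len(array_seq)
    insert_at = int(rng.integers(1000, backbone_len - 1000))
    backbone = decode_nt(_sample_bases(rng, backbone_len, gc))
    host_seq = backbone[:insert_at] + array_seq + backbone[insert_at:]
    host = SequenceRecord("synthetic_host", host_seq)
    # spacer coordinates on the host, 1-based inclusive
    final_rows = []
    off = insert_at + repeat_len  # 0-based start of spacer 1
    for (idx, from_donor, dpos, dstrand, m), sp in zip(truth_rows, spacers):
        final_rows.append((idx, off + 1, off + len(sp), from_donor, dpos, dstrand, m))
        off += len(sp) + repeat_len
    truth = pd.DataFrame(
        final_rows,
        columns=[
            "spacer_index", "start", "end", "from_donor",
            "donor_pos", "donor_strand", "mismatches",
        ],
    )
    return CrisprHost(
        host, truth, insert_at + 1, insert_at + len(array_seq), repeat, spacers
    )


# ---------------------------------------------------------------------------
# mutation ladders / clades (for SG and tree experiments)
# ---------------------------------------------------------------------------

def mutate_genome(genome: SequenceRecord, rate: float, seed: int) -> SequenceRecord:
    """An i.i.d. substitution-mutated copy (no indels)."""
    if not 0 <= rate <= 1:
        raise ParameterError("rate must be in [0, 1]")
    rng = _rng(seed, 4)
    arr = encode_nt(genome.seq).copy()
    mask = rng.random(len(arr)) < rate
    idx = np.nonzero(mask)[0]
    arr[idx] = (arr[idx] + rng.integers(1, 4, len(idx))) % 4
    return SequenceRecord(
        f"{genome.id}_mut", decode_nt(arr), topology=genome.topology,
        description=f"substitution rate {rate}",
    )


def make_clade_genomes(
    n_clades: int = 3,
    per_clade: int = 4,
    length: int = 12_000,
    gc: float = 0.4,
    n_genes: int = 12,
    intra_rate: float = 0.04,
    seed: int = 0,
) -> tuple[dict[str, SequenceRecord], dict[str, int]]:
    """Independent clade ancestors with mutation-derived members; the
    returned label map gives each genome's generating clade."""
    genomes: dict[str, SequenceRecord] = {}
    labels: dict[str, int] = {}
    for c in range(n_clades):
        anc = make_genome(length, gc, n_genes, seed=int(_rng(seed, 5, c).integers(2**31)),
                          genome_id=f"clade{c}_anc").genome
        for m in range(per_clade):
            gid = f"clade{c}_g{m}"
            g = mutate_genome(anc, intra_rate, seed=int(_rng(seed, 6, c, m).integers(2**31)))
            genomes[gid] = SequenceRecord(gid, g.seq, topology="circular")
            labels[gid] = c
    return genomes, labels
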