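"""Sequence I/O and elementary sequence operations.

This module owns the two record types the rest of the pipeline passes
around (:class:`SequenceRecord`, :class:`OrfCall`), readers/writers for
FASTA, FASTQ and GenBank flat files, and the small set of sequence
primitives everything else is built on: G+C content, reverse
complementation, six-frame translation and a naive maximal-ORF scanner.

Conventions
-----------
* Internal coordinates are 0-based half-open; anything written to a
  tabular report is converted to 1-based inclusive at the point of
  output.
* Nucleotide sequences are uppercased on input, ``U`` is mapped to ``T``
  and soft-masked (lowercase) bases are retained after uppercasing.
* The genetic code defaults to the bacterial/archaeal table 11,
  configurable by NCBI table id.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    FormatError,
    MoleculeTypeError,
    ParameterError,
    UndefinedValueError,
)

NT_LETTERS = set("ACGTN")
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

DEFAULT_TRANSLATION_TABLE = 11

# Encoding used throughout: A=0 C=1 G=2 T=3 N=4.
_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _NT_CODE[_b] = _i
_NT_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_NT_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``topology`` is ``"circular"`` for sequences known to close on
    themselves (phage genomes, trimmed circular contigs) and
    ``"linear"`` otherwise.
    """

    id: str
    seq: str
    topology: Literal["linear", "circular"] = "linear"
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        self.seq = self.seq.upper().replace("U", "T") if self.is_nucleotide_like(
            self.seq
        ) else self.seq.upper()

    @staticmethod
    def is_nucleotide_like(seq: str) -> bool:
        return set(seq.upper().replace("U", "T")) <= NT_LETTERS

    @property
    def is_nucleotide(self) -> bool:
        return set(self.seq) <= NT_LETTERS

    @property
    def is_protein(self) -> bool:
        return not self.is_nucleotide and set(self.seq) <= AA_LETTERS

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrfCall:
    """One maximal ATG-to-stop open reading frame.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the source sequence and include the stop codon when one
    terminates the ORF, so ``(end - start)`` is always divisible by 3.
    ``frame`` is 1..3 for the forward strand and 4..6 for the reverse.
    """

    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    protein: str
    has_stop: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ParameterError("OrfCall requires start < end")
        if (self.end - self.start) % 3:
            raise ParameterError("ORF span must be divisible by 3")


# ---------------------------------------------------------------------------
# encoding / translation primitives
# ---------------------------------------------------------------------------

def encode_nt(seq: str) -> np.ndarray:
    """Encode ACGTN as uint8 0..4. Unknown characters raise."""
    arr = _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise FormatError(f"illegal nucleotide character {bad!r}")
    return arr


def decode_nt(arr: np.ndarray) -> str:
    return _NT_DECODE[arr].tobytes().decode("ascii")


def revcomp_enc(arr: np.ndarray) -> np.ndarray:
    return _NT_COMP[arr][::-1]


def reverse_complement(seq: str) -> str:
    return decode_nt(revcomp_enc(encode_nt(seq)))


@lru_cache(maxsize=8)
def _codon_table(table_id: int) -> np.ndarray:
    """64-entry codon->amino-acid table (stops as ``*``), codon code
    ``16*a + 4*b + c`` in the A/C/G/T encoding."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ParameterError(f"unknown translation table id {table_id}") from exc
    out = np.full(64, ord("X"), dtype=np.uint8)
    letters = "ACGT"
    for code in range(64):
        codon = letters[code >> 4] + letters[(code >> 2) & 3] + letters[code & 3]
        if codon in table.stop_codons:
            out[code] = ord("*")
        else:
            out[code] = ord(table.forward_table[codon])
    return out


def translate_enc(arr: np.ndarray, table_id: int = DEFAULT_TRANSLATION_TABLE) -> str:
    """Translate an encoded nucleotide array (frame already applied);
    trailing 1-2 nt are dropped, codons containing N become ``X``."""
    n = (len(arr) // 3) * 3
    if n == 0:
        return ""
    a = arr[:n].reshape(-1, 3)
    valid = (a < 4).all(axis=1)
    code = a[:, 0].astype(np.int16) * 16 + a[:, 1] * 4 + a[:, 2]
    aa = np.where(valid, _codon_table(table_id)[np.where(valid, code, 0)], ord("X"))
    return aa.astype(np.uint8).tobytes().decode("ascii")


def six_frame_translate(
    rec: SequenceRecord, table_id: int = DEFAULT_TRANSLATION_TABLE
) -> dict[int, str]:
    """Translate ``rec`` in all six frames.

    Returns a mapping from frame label (+1, +2, +3, -1, -2, -3) to the
    protein string; frame -k starts at offset k-1 of the reverse
    complement. Stops are rendered as ``*``.
    """
    if not rec.is_nucleotide:
        raise MoleculeTypeError(f"six_frame_translate requires a nucleotide record, got {rec.id!r}")
    fwd = encode_nt(rec.seq)
    rev = revcomp_enc(fwd)
    out: dict[int, str] = {}
    for k in (1, 2, 3):
        out[k] = translate_enc(fwd[k - 1 :], table_id)
        out[-k] = translate_enc(rev[k - 1 :], table_id)
    return out


def frame_to_forward(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int]:
    """Map a half-open aa interval on a translation frame back to 1-based
    inclusive nucleotide coordinates on the forward strand.

    For minus frames the returned pair has start > end, following the
    aligner tabular convention for reverse-strand subjects.
    """
    k = abs(frame)
    nt_start = (k - 1) + 3 * aa_start  # 0-based on the read strand
    nt_end = (k - 1) + 3 * aa_end  # half-open
    if frame > 0:
        return nt_start + 1, nt_end
    # coordinates were on the reverse complement; reflect
    return seq_len - nt_start, seq_len - nt_end + 1


def gc_content(rec: SequenceRecord) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N is ignored entirely."""
    if not rec.is_nucleotide:
        raise MoleculeTypeError(f"gc_content requires a nucleotide record, got {rec.id!r}")
    arr = encode_nt(rec.seq)
    counts = np.bincount(arr, minlength=5)
    denom = int(counts[:4].sum())
    if denom == 0:
        raise UndefinedValueError(f"G+C content undefined for all-N sequence {rec.id!r}")
    return float(counts[1] + counts[2]) / denom


def naive_orf_scan(
    rec: SequenceRecord,
    min_aa: int,
    table_id: int = DEFAULT_TRANSLATION_TABLE,
    require_stop: bool = True,
) -> list[OrfCall]:
    """All maximal ATG-to-stop ORFs on both strands with protein length
    >= ``min_aa``, sorted by forward-strand start coordinate.

    A maximal ORF opens at the first ATG following the previous in-frame
    stop. This is deliberately naive plumbing: it is used to derive
    proteomes for synthetic genomes, while real proteomes come from
    annotation (GenBank CDS translations).
    """
    if not rec.is_nucleotide:
        raise MoleculeTypeError("naive_orf_scan requires a nucleotide record")
    L = len(rec.seq)
    fwd = encode_nt(rec.seq)
    rev = revcomp_enc(fwd)
    calls: list[OrfCall] = []
    for strand, arr in (("+", fwd), ("-", rev)):
        for k in (1, 2, 3):
            aa = translate_enc(arr[k - 1 :], table_id)
            frame = k if strand == "+" else k + 3
            prev_stop = -1  # codon index of previous stop
            i = 0
            n = len(aa)
            while i <= n:
                stop = aa.find("*", max(prev_stop + 1, i))
                seg_end = stop if stop != -1 else n
                m = aa.find("M", prev_stop + 1, seg_end)
                if m != -1:
                    prot = aa[m:seg_end]
                    if len(prot) >= min_aa and (stop != -1 or not require_stop):
                        c_start = (k - 1) + 3 * m
                        c_end = (k - 1) + 3 * (seg_end + (1 if stop != -1 else 0))
                        if strand == "+":
                            s, e = c_start, c_end
                        else:
                            s, e = L - c_end, L - c_start
                        calls.append(
                            OrfCall(s, e, strand, frame, prot, has_stop=stop != -1)
                        )
                if stop == -1:
                    break
                prev_stop = stop
                i = stop + 1
    calls.sort(key=lambda c: (c.start, c.end, c.frame))
    return calls


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _check_alphabet(records: list[SequenceRecord], path: Path, moltype: str) -> None:
    for rec in records:
        if moltype == "nt" or (moltype == "auto" and rec.is_nucleotide):
            bad = set(rec.seq) - NT_LETTERS
        else:
            bad = set(rec.seq) - AA_LETTERS
        if bad:
            line = _find_offending_line(path, bad)
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in record {rec.id!r}", line=line
            )


def _find_offending_line(path: Path, bad: set[str]) -> int | None:
    try:
        with open(path) as fh:
            for i, raw in enumerate(fh, 1):
                if raw.startswith((">", "@", "+")):
                    continue
                if bad & set(raw.strip().upper().replace("U", "T")):
                    return i
    except OSError:  # pragma: no cover
        return None
    return None


def _ensure_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path, moltype: str = "auto") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    ``moltype`` is ``"nt"``, ``"aa"`` or ``"auto"`` (per-record guess:
    a sequence over A/C/G/T/U/N is taken as nucleotide). Sequences are
    uppercased and U is mapped to T in nucleotide mode.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq).upper()
        if moltype == "nt" or (moltype == "auto" and SequenceRecord.is_nucleotide_like(seq)):
            seq = seq.replace("U", "T")
        if not seq:
            raise FormatError(f"record {sr.id!r} has an empty sequence")
        records.append(SequenceRecord(sr.id, seq, description=sr.description))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    _ensure_unique_ids(records)
    _check_alphabet(records, path, moltype)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}"
            )
            if rec.topology == "circular" and "topology=circular" not in header:
                header += " topology=circular"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line-per-record FASTQ; qualities are validated (length must
    equal sequence length) and then discarded."""
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                break
            lineno += 1
            if not head.startswith("@"):
                raise FormatError("expected '@' header", line=lineno)
            seq_line = fh.readline()
            plus = fh.readline()
            qual_line = fh.readline()
            if not seq_line or not plus or not qual_line:
                raise FormatError("truncated FASTQ record", line=lineno)
            seq = seq_line.rstrip("\n")
            qual = qual_line.rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError("expected '+' separator", line=lineno + 2)
            if not seq or not qual:
                raise FormatError("truncated FASTQ record", line=lineno)
            if len(qual) != len(seq):
                raise FormatError(
                    f"quality length {len(qual)} != sequence length {len(seq)}",
                    line=lineno + 3,
                )
            rid = head[1:].split()[0]
            records.append(
                SequenceRecord(rid, seq.upper().replace("U", "T"), description=head[1:].strip())
            )
            lineno += 3
    if not records:
        raise EmptyInputError(f"no FASTQ records in {path}")
    _ensure_unique_ids(records)
    _check_alphabet(records, path, "nt")
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual_char * len(rec.seq)}\n")


def read_genbank(
    path: str | Path,
) -> tuple[SequenceRecord, list[tuple[SequenceRecord, tuple[int, int, str]]]]:
    """Read one GenBank flat-file record: the genome sequence plus the
    annotated proteome.

    Returns ``(genome, proteins)`` where each protein entry is a
    ``(record, (start, end, strand))`` pair with 0-based half-open
    genome coordinates. CDS translations are taken from the annotation
    rather than re-predicted.
    """
    path = Path(path)
    try:
        sr = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise EmptyInputError(f"no GenBank records in {path}") from None
    topology = "circular" if sr.annotations.get("topology") == "circular" else "linear"
    genome = SequenceRecord(sr.id, str(sr.seq).upper(), topology=topology,
                            description=sr.description)
    proteins: list[tuple[SequenceRecord, tuple[int, int, str]]] = []
    n = 0
    for feat in sr.features:
        if feat.type != "CDS":
            continue
        trans = feat.qualifiers.get("translation", [None])[0]
        if not trans:
            continue
        n += 1
        pid = feat.qualifiers.get("protein_id", [f"{sr.id}_p{n:03d}"])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        proteins.append(
            (
                SequenceRecord(pid, trans, description=f"{sr.id} CDS {n}"),
                (int(feat.location.start), int(feat.location.end), strand),
            )
        )
    return genome, proteins
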