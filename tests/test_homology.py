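"""homology: translated searches, mismatch scanning, E-values, tabular IO."""

import math

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from viromine import homology as H
from viromine._scoring import bitscore, evalue
from viromine.errors import EmptyInputError, FormatError, ParameterError
from viromine.seqio import SequenceRecord, reverse_complement, six_frame_translate

AAS = list("ACDEFGHIKLMNPQRSTVWY")
PERMISSIVE = dict(evalue_max=1e9, min_identity_pct=0.0)


def _oracle_best_frame_score(query: str, subject: str) -> float:
    """Exhaustive per-frame local alignment optimum via an independent
    dynamic-programming aligner (affine gaps 11/1, BLOSUM62)."""
    al = Align.PairwiseAligner(mode="local", open_gap_score=-12, extend_gap_score=-1)
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    frames = six_frame_translate(SequenceRecord("s", subject))
    return max(al.score(query, f) for f in frames.values() if f)


class TestProteinVsDna:
    def test_planted_translation_found_exactly(self):
        rng = np.random.default_rng(7)
        genome = "".join(rng.choice(list("ACGT"), 2_000))
        # plant at a frame-2 position
        start = 601
        segment = genome[start : start + 150]
        query = str(six_frame_translate(SequenceRecord("t", segment))[1])
        hits = H.search_protein_vs_dna(
            SequenceRecord("q", query), [SequenceRecord("s", genome)]
        )
        top = hits[0]
        assert top.percent_identity == 100.0
        assert top.aln_length == 50
        assert top.frame == (start % 3) + 1
        assert top.s_start == start + 1 and top.s_end == start + 150

    def test_random_queries_pass_no_evalue_filter(self):
        rng = np.random.default_rng(0)
        subject = SequenceRecord("s", "".join(rng.choice(list("ACGT"), 1_000)))
        empty = 0
        for _ in range(20):
            q = SequenceRecord("q", "".join(rng.choice(AAS, 120)))
            if not H.search_protein_vs_dna(q, [subject]):
                empty += 1
        assert empty >= 19  # >= 95% of shuffles yield nothing at E <= 1e-3

    def test_engine_matches_exhaustive_dp_on_planted_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            genome = "".join(rng.choice(list("ACGT"), 800))
            start = int(rng.integers(0, 500))
            prot = str(six_frame_translate(SequenceRecord("t", genome[start : start + 120]))[1])
            hits = H.search_protein_vs_dna(
                SequenceRecord("q", prot), [SequenceRecord("s", genome)],
                H.SearchParams(**PERMISSIVE),
            )
            assert hits[0].raw_score == _oracle_best_frame_score(prot, genome)

    def test_short_query_and_empty_db_rejected(self):
        with pytest.raises(ParameterError):
            H.search_protein_vs_dna(SequenceRecord("q", "MK"), [SequenceRecord("s", "ACGTACGT")])
        with pytest.raises(EmptyInputError):
            H.search_protein_vs_dna(SequenceRecord("q", "MKLFWYARN"), [])


@pytest.fixture(scope="module")
def proteome(genome20k):
    return genome20k.proteins


class TestDnaVsProtein:
    def test_verbatim_coding_read_hits_source(self, genome20k, proteome):
        s, e, strand = genome20k.protein_locs[proteome[0].id]
        read = SequenceRecord("r", genome20k.genome.seq[s + 3 : s + 153])
        best = H.search_dna_vs_protein(read, proteome)
        assert best is not None
        assert best.subject_id == proteome[0].id
        assert best.percent_identity == 100.0

    def test_intergenic_read_unmatched(self, genome20k, proteome):
        # a read of non-coding sequence assembled from gene-free gaps
        occupied = np.zeros(len(genome20k.genome.seq), bool)
        for s, e, _ in genome20k.protein_locs.values():
            occupied[max(0, s - 3) : e + 3] = True
        free = "".join(
            b for b, occ in zip(genome20k.genome.seq, occupied) if not occ
        )[:120]
        assert H.search_dna_vs_protein(SequenceRecord("r", free), proteome) is None

    def test_noisy_reads_recover_source_protein(self, genome20k, proteome):
        """250-nt coding reads with 5% substitutions: the single best
        reciprocal hit is the source protein in >= 95% of 1,000 reads."""
        rng = np.random.default_rng(42)
        locs = list(genome20k.protein_locs.items())
        ok = 0
        n = 1_000
        arr = np.frombuffer(genome20k.genome.seq.encode(), np.uint8)
        for _ in range(n):
            pid, (s, e, strand) = locs[rng.integers(len(locs))]
            if e - s < 250:
                ok += 1  # skip genes too short for the read length
                continue
            start = int(rng.integers(s, e - 250))
            read = bytearray(arr[start : start + 250])
            for i in np.nonzero(rng.random(250) < 0.05)[0]:
                read[i] = ord(rng.choice([b for b in "ACGT" if b != chr(read[i])]))
            best = H.search_dna_vs_protein(SequenceRecord("r", bytes(read).decode()), proteome)
            if best is not None and best.subject_id == pid:
                ok += 1
        assert ok / n >= 0.95


class TestScanWithMismatches:
    def test_planted_exact_pattern(self):
        rng = np.random.default_rng(5)
        bg = "".join(rng.choice(list("ACGT"), 5_000))
        pat = "".join(rng.choice(list("ACGT"), 30))
        subject = SequenceRecord("s", bg[:2000] + pat + bg[2000:])
        matches = H.scan_with_mismatches(pat, subject, max_mm=0)
        assert matches == [(2001, "+", 0)]

    def test_single_mismatch_38mer(self):
        rng = np.random.default_rng(6)
        bg = "".join(rng.choice(list("ACGT"), 4_000))
        pat = "".join(rng.choice(list("ACGT"), 38))
        mutated = list(pat)
        mutated[17] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[17]]
        subject = SequenceRecord("s", bg[:1500] + "".join(mutated) + bg[1500:])
        matches = H.scan_with_mismatches(pat, subject, max_mm=2)
        assert matches == [(1501, "+", 1)]

    def test_absent_pattern_empty(self):
        subject = SequenceRecord("s", "ACGT" * 100)
        assert H.scan_with_mismatches("TTTTTTTTTTTTTTTG", subject, max_mm=0) == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 3_000))
        pat = seq[700:735]
        subject = SequenceRecord("s", seq)
        flipped = SequenceRecord("s", reverse_complement(seq))
        fwd = H.scan_with_mismatches(pat, subject, max_mm=1)
        rev = H.scan_with_mismatches(pat, flipped, max_mm=1)
        assert len(fwd) == len(rev)
        L, plen = len(seq), len(pat)
        reflected = sorted(
            (L - p - plen + 2, {"+": "-", "-": "+"}[s], m) for p, s, m in fwd
        )
        assert reflected == sorted(rev)

    def test_circular_subject_scanned_across_origin(self):
        rng = np.random.default_rng(9)
        core = "".join(rng.choice(list("ACGT"), 500))
        pat = core[-10:] + core[:10]  # spans the origin
        matches = H.scan_with_mismatches(
            pat, SequenceRecord("s", core, topology="circular"), max_mm=0
        )
        assert (491, "+", 0) in matches

    def test_bad_pattern_rejected(self):
        s = SequenceRecord("s", "ACGT" * 50)
        with pytest.raises(FormatError):
            H.scan_with_mismatches("ACGTACGTACGTACG!", s, 0)
        with pytest.raises(ParameterError):
            H.scan_with_mismatches("ACGTACGTACGTACGT", s, max_mm=10)


class TestStatistics:
    def test_evalue_strictly_decreases_with_bitscore(self):
        evs = [evalue(raw, 200, 50_000, 10, gapped=False) for raw in range(40, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_bitscore_is_affine_in_raw_score(self):
        b1, b2, b3 = (bitscore(r, gapped=True) for r in (50, 60, 70))
        assert b2 - b1 == pytest.approx(b3 - b2)


class TestTabular:
    def _hit(self, i):
        return H.AlignmentHit(
            f"q{i}", f"s{i}", 97.5, 50, 1, 0, 1, 50, 101, 250, 1.5e-20, 105.3
        )

    def test_three_hit_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        H.write_tabular_hits([self._hit(i) for i in range(3)], p)
        assert len(H.read_tabular_hits(p)) == 3

    def test_round_trip_preserves_fields(self, tmp_path):
        rng = np.random.default_rng(1)
        hits = [
            H.AlignmentHit(
                f"q{i}", f"s{i % 7}", float(np.round(rng.uniform(30, 100), 3)),
                int(rng.integers(20, 400)), int(rng.integers(0, 20)),
                int(rng.integers(0, 3)), 1, 50, 10, 200,
                float(10.0 ** -rng.integers(3, 40)), float(np.round(rng.uniform(30, 500), 1)),
            )
            for i in range(1_000)
        ]
        p = tmp_path / "big.tsv"
        H.write_tabular_hits(hits, p)
        back = H.read_tabular_hits(p)
        assert len(back) == 1_000
        for a, b in zip(hits, back):
            assert (a.query_id, a.subject_id, a.aln_length, a.mismatches,
                    a.gap_opens, a.q_start, a.q_end, a.s_start, a.s_end) == (
                b.query_id, b.subject_id, b.aln_length, b.mismatches,
                b.gap_opens, b.q_start, b.q_end, b.s_start, b.s_end)
            assert b.percent_identity == pytest.approx(a.percent_identity, abs=1e-3)
            assert b.evalue == pytest.approx(a.evalue, rel=1e-2)
            assert b.bitscore == pytest.approx(a.bitscore, abs=0.05)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        H.write_tabular_hits([self._hit(0)], p)
        with open(p, "a") as fh:
            fh.write("q\ts\t100.0\n")
        with pytest.raises(FormatError) as exc:
            H.read_tabular_hits(p)
        assert exc.value.line == 2
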