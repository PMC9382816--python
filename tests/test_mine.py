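"""mine: length filtering, circularization, SG score, tree, classification."""

import io

import numpy as np
import pytest
import skbio

from viromine import mine, simulate as sim
from viromine.errors import ContractError, ParameterError, UndefinedValueError
from viromine.seqio import SequenceRecord


def _contig(cid, length, seed=0):
    rng = np.random.default_rng([seed, length])
    return mine.ContigRecord(
        SequenceRecord(cid, "".join(rng.choice(list("ACGT"), length)))
    )


class TestFilterContigs:
    @pytest.mark.parametrize(
        "length,kept", [(9_999, False), (10_000, True), (200_000, True), (200_001, False)]
    )
    def test_inclusive_boundaries(self, length, kept):
        out = mine.filter_contigs([_contig("c", length)])
        assert bool(out) is kept

    def test_counted_construction(self):
        rng = np.random.default_rng(17)
        lengths = rng.integers(2_000, 250_000, 100)
        contigs = [_contig(f"c{i}", int(L)) for i, L in enumerate(lengths)]
        expected = int(((lengths >= 10_000) & (lengths <= 200_000)).sum())
        kept = mine.filter_contigs(contigs)
        assert len(kept) == expected
        assert [c.id for c in kept] == [c.id for c in contigs if 10_000 <= len(c) <= 200_000]

    def test_bad_band_rejected(self):
        with pytest.raises(ParameterError):
            mine.filter_contigs([], min_len=100, max_len=50)


class TestDetectCircularity:
    def test_planted_terminal_repeat(self, genome20k):
        contig = sim.make_circular_contig(genome20k.genome, 55)
        is_circ, k, trimmed = mine.detect_circularity(contig)
        assert is_circ and k == 55
        assert trimmed.seq == genome20k.genome.seq
        assert trimmed.topology == "circular"

    def test_random_contig_linear(self):
        c = _contig("lin", 30_000, seed=2)
        is_circ, k, trimmed = mine.detect_circularity(c)
        assert not is_circ and k < 20
        assert trimmed.seq == c.seq and trimmed.topology == "linear"

    def test_overlap_exactly_min_overlap_is_circular(self, genome20k):
        contig = sim.make_circular_contig(genome20k.genome, 20)
        is_circ, k, _ = mine.detect_circularity(contig, min_overlap=20)
        assert is_circ and k == 20

    def test_trim_is_exact_inverse(self, genome20k):
        for ov in (20, 37, 120):
            contig = sim.make_circular_contig(genome20k.genome, ov)
            is_circ, k, trimmed = mine.detect_circularity(contig)
            assert is_circ
            assert trimmed.seq + trimmed.seq[:k] == contig.seq

    def test_too_short_contig_rejected(self):
        with pytest.raises(ParameterError):
            mine.detect_circularity(_contig("s", 30), min_overlap=20)


class TestComputeSg:
    def test_self_similarity_is_exactly_one(self, genome20k):
        assert mine.compute_sg(genome20k.genome, genome20k.genome) == 1.0

    def test_unrelated_genomes_near_zero(self):
        """Independent random 20-kb genomes score SG < 0.01 (10 seeds)."""
        for seed in range(10):
            a = sim.make_genome(20_000, 0.4, 18, seed=7_000 + seed, genome_id="a").genome
            b = sim.make_genome(20_000, 0.4, 18, seed=8_000 + seed, genome_id="b").genome
            assert mine.compute_sg(a, b) < 0.01

    def test_symmetric_by_construction(self, genome20k):
        other = sim.mutate_genome(genome20k.genome, 0.1, seed=3)
        other = SequenceRecord("zz_other", other.seq)
        ab = mine.compute_sg(genome20k.genome, other)
        ba = mine.compute_sg(other, genome20k.genome)
        assert ab == ba > 0

    def test_monotone_under_mutation_ladder(self):
        g = sim.make_genome(12_000, 0.4, 11, seed=12, genome_id="base").genome
        self_g = mine.sg_self_score(g)
        values = []
        for rate in (0.0, 0.05, 0.1, 0.2, 0.3, 0.4):
            m = SequenceRecord("zz_m", sim.mutate_genome(g, rate, seed=44).seq)
            values.append(mine.compute_sg(g, m, self_a=self_g))
        assert values[0] == 1.0
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_short_genome_rejected_and_orfless_undefined(self):
        with pytest.raises(ParameterError):
            mine.compute_sg(SequenceRecord("a", "ACGT" * 100), SequenceRecord("b", "ACGT" * 100))
        blank = SequenceRecord("n", "N" * 2_000)
        with pytest.raises(UndefinedValueError):
            mine.compute_sg(blank, blank)


def _tree_from_newick(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(io.StringIO(newick), convert_underscores=False)


class TestBuildTree:
    def test_dominant_pair_topology(self):
        m = mine.SGMatrix(
            ["A", "B", "C"],
            np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]]),
        )
        tree = _tree_from_newick(mine.build_tree(m))
        ab = tree.lowest_common_ancestor(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_identical_genomes_zero_length_cherry(self, genome20k):
        a = genome20k.genome
        a2 = SequenceRecord("g20kb", a.seq, topology="circular")
        c = sim.make_genome(12_000, 0.5, 11, seed=31, genome_id="zz").genome
        m = mine.sg_matrix([a, a2, c])
        tree = _tree_from_newick(mine.build_tree(m))
        cherry = tree.lowest_common_ancestor(["g20k", "g20kb"])
        tips = {t.name: t for t in cherry.tips()}
        assert set(tips) == {"g20k", "g20kb"}
        assert all(t.length == pytest.approx(0.0, abs=1e-9) for t in tips.values())

    def test_ultrametric_matrix_topology_recovered(self):
        # three clades of two, SG 0.8 within, 0.2/0.05 between
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        m = np.full((6, 6), 0.05)
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            m[i, j] = m[j, i] = 0.8
        m[0:4, 0:4] = np.where(m[0:4, 0:4] == 0.05, 0.2, m[0:4, 0:4])
        np.fill_diagonal(m, 1.0)
        tree = _tree_from_newick(mine.build_tree(mine.SGMatrix(ids, m)))
        for pair in (["a1", "a2"], ["b1", "b2"], ["c1", "c2"]):
            lca = tree.lowest_common_ancestor(pair)
            assert {t.name for t in lca.tips()} == set(pair)
        ab = tree.lowest_common_ancestor(["a1", "b1"])
        assert {t.name for t in ab.tips()} == {"a1", "a2", "b1", "b2"}

    def test_contract_checks(self):
        bad = np.array([[1.0, 0.5, 0.1], [0.4, 1.0, 0.1], [0.1, 0.1, 1.0]])
        with pytest.raises(ContractError):
            mine.SGMatrix(["A", "B", "C"], bad)
        m = mine.SGMatrix(["A", "B"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        with pytest.raises(ParameterError):
            mine.build_tree(m)


class TestClassifyContigs:
    def test_reference_copy_scores_one(self, genome20k):
        panel = {"g20k": genome20k.genome,
                 "other": sim.make_genome(12_000, 0.5, 11, seed=31, genome_id="other").genome}
        contig = mine.ContigRecord(SequenceRecord("copy", genome20k.genome.seq))
        report = mine.classify_contigs([contig], panel, {"g20k"})
        row = report.iloc[0]
        assert row.nearest_reference == "g20k"
        assert row.sg == 1.0
        assert row.verdict == "virtual cyanophage"

    def test_random_contig_below_floor(self, genome20k):
        panel = {"g20k": genome20k.genome}
        contig = mine.ContigRecord(
            SequenceRecord("rand", sim.make_genome(15_000, 0.4, 14, seed=9_191,
                                                   genome_id="r").genome.seq)
        )
        report = mine.classify_contigs([contig], panel, {"g20k"})
        assert report.iloc[0].sg < mine.SG_FLOOR
        assert report.iloc[0].verdict == "unclassified"

    def test_mutated_copy_finds_source_among_many_references(self, genome20k):
        """A 30%-mutated copy of a cyanophage reference among 10
        unrelated references is classified nearest to its source."""
        panel = {"cyano_src": genome20k.genome}
        for i in range(10):
            g = sim.make_genome(10_000, 0.45, 9, seed=6_500 + i,
                                genome_id=f"ref{i:02d}").genome
            panel[g.id] = g
        mutated = sim.mutate_genome(genome20k.genome, 0.30, seed=18)
        contig = mine.ContigRecord(SequenceRecord("mut30", mutated.seq))
        report = mine.classify_contigs([contig], panel, {"cyano_src"})
        assert report.iloc[0].nearest_reference == "cyano_src"

    def test_classifier_score_filter_and_empty_panel(self, genome20k):
        contig = mine.ContigRecord(
            SequenceRecord("c", genome20k.genome.seq), phage_score=0.1
        )
        report = mine.classify_contigs([contig], {"g20k": genome20k.genome}, {"g20k"})
        assert len(report) == 0
        with pytest.raises(ParameterError):
            mine.classify_contigs([contig], {}, set())
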