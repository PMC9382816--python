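"""recruit: reciprocal best-hit assignment, abundance, coverage."""

import numpy as np
import pandas as pd
import pytest

from viromine import recruit as rc, simulate as sim
from viromine.errors import ParameterError, UndefinedValueError
from viromine.homology import AlignmentHit
from viromine.seqio import SequenceRecord


def _result_with_counts(counts: dict[str, int], lengths: dict[str, int]):
    """Hand-build a RecruitmentResult with the given assigned counts."""
    hit = AlignmentHit("p", "r", 100.0, 50, 0, 0, 1, 50, 1, 150, 1e-20, 100.0)
    assignments = []
    i = 0
    for pid, n in counts.items():
        for _ in range(n):
            assignments.append(
                rc.ReadAssignment(f"read_{i}", "assigned", pid, hit, hit)
            )
            i += 1
    return rc.RecruitmentResult(assignments, list(counts))


def _refs_with_lengths(lengths: dict[str, int]):
    phages = [
        rc.ReferencePhage(
            pid, SequenceRecord(pid, "ACGT" * (L // 4)),
            [SequenceRecord(f"{pid}_p001", "M" + "K" * 60)],
        )
        for pid, L in lengths.items()
    ]
    return rc.ReferenceSet(phages)


class TestRecruitReads:
    def test_planted_coding_reads_all_assigned_to_source(self, genome20k):
        """Reads copied verbatim from coding regions, decoys unrelated:
        every read is assigned to its source phage."""
        other = sim.make_genome(12_000, 0.5, 11, seed=55, genome_id="other")
        refs = rc.ReferenceSet(
            [
                rc.ReferencePhage("g20k", genome20k.genome, genome20k.proteins,
                                  genome20k.protein_locs),
                rc.ReferencePhage("other", other.genome, other.proteins,
                                  other.protein_locs),
            ]
        )
        decoys = sim.make_genome(12_000, 0.4, 11, seed=77, genome_id="dec").proteins
        reads = []
        truth = []
        for src in (genome20k, other):
            for pid, (s, e, strand) in list(src.protein_locs.items())[:10]:
                reads.append(SequenceRecord(f"r{len(reads)}", src.genome.seq[s : s + 150]))
                truth.append(src.genome.id)
        result = rc.recruit_reads(reads, refs, decoys)
        assert result.counts["assigned"] == len(reads)
        for a, src in zip(result.assignments, truth):
            assert a.phage == src
            assert a.forward_hit is not None and a.reciprocal_hit is not None

    def test_empty_read_list(self, small_community):
        result = rc.recruit_reads([], small_community.refs, small_community.decoy_proteins)
        assert result.counts == {"assigned": 0, "unassigned": 0, "ambiguous": 0}

    def test_empty_proteome_rejected_and_empty_decoys_warn(self, small_community):
        refs = rc.ReferenceSet(
            [rc.ReferencePhage("x", SequenceRecord("x", "ACGT" * 100), [])]
        )
        with pytest.raises(ParameterError):
            rc.recruit_reads(small_community.reads[:5], refs, [])
        with pytest.warns(UserWarning, match="decoy"):
            rc.recruit_reads(
                small_community.reads[:5], small_community.refs, []
            )

    def test_conservation_and_decoy_rejection(self, small_community, small_recruitment):
        """Statuses partition the read set; decoy-origin reads almost
        never end up assigned, target reads almost never mis-assigned."""
        res = small_recruitment
        counts = res.counts
        assert sum(counts.values()) == len(small_community.reads)
        truth = small_community.truth.set_index("read_id")["source"]
        decoy_total = decoy_bad = mis = target_assigned = 0
        for a in res.assignments:
            src = truth[a.read_id]
            if src.startswith("decoy"):
                decoy_total += 1
                if a.status == "assigned":
                    decoy_bad += 1
            elif a.status == "assigned":
                target_assigned += 1
                if a.phage != src:
                    mis += 1
        assert decoy_total > 0
        assert decoy_bad / decoy_total <= 0.01  # >= 99% rejected
        assert mis / max(target_assigned, 1) <= 0.01


class TestComputeAbundance:
    def test_analytically_forced_fractions(self):
        lengths = {"a": 10_000, "b": 20_000}
        result = _result_with_counts({"a": 100, "b": 100}, lengths)
        table = rc.compute_abundance(result, _refs_with_lengths(lengths))
        fr = table.fractions()
        assert fr["a"] == pytest.approx(2 / 3)
        assert fr["b"] == pytest.approx(1 / 3)

    def test_counts_proportional_to_length_gives_equal_fractions(self):
        lengths = {"a": 8_000, "b": 16_000, "c": 24_000}
        result = _result_with_counts({"a": 80, "b": 160, "c": 240}, lengths)
        fr = rc.compute_abundance(result, _refs_with_lengths(lengths)).fractions()
        assert all(v == pytest.approx(1 / 3) for v in fr.values())

    def test_fractions_sum_to_one_and_scale_invariant(self):
        lengths = {"a": 9_000, "b": 13_000, "c": 21_000}
        f1 = rc.compute_abundance(
            _result_with_counts({"a": 30, "b": 50, "c": 20}, lengths),
            _refs_with_lengths(lengths),
        ).fractions()
        f5 = rc.compute_abundance(
            _result_with_counts({"a": 150, "b": 250, "c": 100}, lengths),
            _refs_with_lengths(lengths),
        ).fractions()
        assert sum(f1.values()) == pytest.approx(1.0)
        for k in f1:
            assert f1[k] == pytest.approx(f5[k])

    def test_no_assigned_reads_undefined(self):
        lengths = {"a": 8_000}
        result = _result_with_counts({"a": 0}, lengths)
        with pytest.raises(UndefinedValueError):
            rc.compute_abundance(result, _refs_with_lengths(lengths))

    def test_spiked_recovery_small_community(self, small_community, small_recruitment):
        est = rc.compute_abundance(small_recruitment, small_community.refs).percents()
        spiked = {"p1": 50.0, "p2": 30.0, "p3": 20.0}
        for pid, pct in spiked.items():
            assert est[pid] == pytest.approx(pct, abs=2.5)

    def test_estimated_fraction_monotone_in_spiked_proportion(self):
        """Raising one phage's spiked proportion (others in fixed
        ratio) never lowers its estimated fraction."""
        genomes = {}
        phages = []
        for i, pid in enumerate(["m1", "m2", "m3"]):
            g = sim.make_genome(10_000, 0.4, 9, seed=300 + i, coding_nt=7_000,
                                genome_id=pid)
            genomes[pid] = g
            phages.append(g)
        estimates = []
        for a1 in (0.2, 0.45, 0.7):
            rest = (1 - a1) / 2
            spec = sim.CommunitySpec(
                phages=[
                    sim.PhageSpec("m1", 10_000, 0.4, a1),
                    sim.PhageSpec("m2", 10_000, 0.4, rest),
                    sim.PhageSpec("m3", 10_000, 0.4, rest),
                ],
                n_reads=2_500,
                seed=21,
                decoy_fraction=0.0,
            )
            reads, _ = sim.make_reads({p.genome.id: p.genome for p in phages}, spec)
            refs = rc.ReferenceSet(
                [rc.ReferencePhage(p.genome.id, p.genome, p.proteins, p.protein_locs)
                 for p in phages]
            )
            decoys = sim.make_genome(10_000, 0.45, 9, seed=400, genome_id="d").proteins
            res = rc.recruit_reads(reads, refs, decoys)
            estimates.append(rc.compute_abundance(res, refs).fractions()["m1"])
        assert estimates[0] <= estimates[1] <= estimates[2]


class TestCoverageMap:
    def test_single_assigned_read_single_interval(self, genome20k):
        refs = rc.ReferenceSet(
            [rc.ReferencePhage("g20k", genome20k.genome, genome20k.proteins,
                               genome20k.protein_locs)]
        )
        pid, (s, e, strand) = next(iter(genome20k.protein_locs.items()))
        read = SequenceRecord("r0", genome20k.genome.seq[s : s + 150])
        decoys = sim.make_genome(12_000, 0.4, 11, seed=78, genome_id="d2").proteins
        res = rc.recruit_reads([read], refs, decoys)
        tracks = rc.coverage_map(res, refs)
        assert len(tracks["g20k"]) == 1
        lo, hi, ident = tracks["g20k"][0]
        assert s <= lo < hi <= e
        assert 30.0 <= ident <= 100.0

    def test_no_assigned_reads_empty_track(self, small_community, small_recruitment):
        tracks = rc.coverage_map(small_recruitment, small_community.refs)
        assert set(tracks) == {"p1", "p2", "p3"}

    def test_dense_genome_tiled_at_depth(self):
        """Error-free reads at ~20x depth over a gene-dense genome:
        coverage intervals tile >= 95% of the genome."""
        g = sim.make_genome(21_000, 0.4, 26, seed=6, gene_len_range=(240, 280),
                            coding_nt=20_350, genome_id="dense")
        spec = sim.CommunitySpec(
            phages=[sim.PhageSpec("dense", 21_000, 0.4, 1.0)],
            n_reads=2_800, substitution_error_rate=0.0, decoy_fraction=0.0, seed=13,
        )
        reads, _ = sim.make_reads({"dense": g.genome}, spec)
        refs = rc.ReferenceSet(
            [rc.ReferencePhage("dense", g.genome, g.proteins, g.protein_locs)]
        )
        decoys = sim.make_genome(12_000, 0.4, 11, seed=79, genome_id="d3").proteins
        res = rc.recruit_reads(reads, refs, decoys)
        covered = np.zeros(21_000, bool)
        for lo, hi, _ident in rc.coverage_map(res, refs)["dense"]:
            covered[lo:hi] = True
        assert covered.mean() >= 0.95
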