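#!/usr/bin/env python
"""Mine virtual phage genomes from a synthetic contig pool.

Builds a contig pool with known truth — circular contigs (reference
genomes with terminal direct repeats re-appended), mutated relatives
of the references, and unrelated decoy contigs — then runs the mining
cascade: 10-200 kb length band, terminal-repeat circularization, SG
classification against the reference panel, and the UPGMA proteomic
dendrogram. Writes results/mine_classification.tsv,
results/sg_matrix.tsv and results/sg_tree.nwk.
"""

import argparse
from pathlib import Path

from viromine import mine, simulate as sim
from viromine.seqio import SequenceRecord

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    # small reference panel (desk-scale genome sizes keep SG fast)
    panel = {}
    for i in range(3):
        g = sim.make_genome(16_000, 0.4, 15, seed=args.seed + i,
                            genome_id=f"ref{i + 1}").genome
        panel[g.id] = g
    cyano_ids = {"ref1", "ref2"}

    contigs = []
    # circular contigs derived from the panel (terminal repeats 30-120 bp)
    for j, (rid, g) in enumerate(sorted(panel.items())):
        mut = sim.mutate_genome(g, 0.10, seed=1000 + j)
        mut = SequenceRecord(f"contig_circ_{rid}", mut.seq)
        contigs.append(sim.make_circular_contig(mut, 30 + 45 * j))
    # linear mutated relative + unrelated decoys + one too-short contig
    rel = sim.mutate_genome(panel["ref1"], 0.2, seed=77)
    contigs.append(mine.ContigRecord(SequenceRecord("contig_rel_ref1", rel.seq)))
    for k in range(2):
        d = sim.make_genome(14_000, 0.5, 13, seed=5_000 + k,
                            genome_id=f"contig_decoy{k + 1}").genome
        contigs.append(mine.ContigRecord(SequenceRecord(d.id, d.seq)))
    short = sim.make_genome(6_000, 0.4, 5, seed=9_999, genome_id="contig_short").genome
    contigs.append(mine.ContigRecord(SequenceRecord(short.id, short.seq)))

    kept = mine.filter_contigs(contigs)
    print(f"{len(kept)}/{len(contigs)} contigs pass the 10-200 kb band "
          f"(dropped: {[c.id for c in contigs if c not in kept]})")
    resolved = [mine.circularize_contig(c) for c in kept]
    for c in resolved:
        if c.is_circular:
            print(f"  {c.id}: circular, terminal repeat {c.terminal_overlap_len} bp, "
                  f"trimmed to {len(c)} bp")

    report = mine.classify_contigs(resolved, panel, cyano_ids)
    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)
    report.to_csv(resdir / "mine_classification.tsv", sep="\t", index=False)
    print(report.to_string(index=False))

    everything = dict(panel)
    everything.update({c.id: c.record for c in resolved})
    m = mine.sg_matrix(everything)
    m.write_tsv(resdir / "sg_matrix.tsv")
    newick = mine.build_tree(m)
    (resdir / "sg_tree.nwk").write_text(newick + "\n")
    print("dendrogram:", newick)


if __name__ == "__main__":
    main()
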