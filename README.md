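# viromine

Reference-guided mining of phage genomes from viral metagenomes.

Freshwater cyanophages — viruses that infect bloom-forming
cyanobacteria — are badly under-sequenced: only a handful of reference
genomes exist, so most of a lake virome cannot be assigned to anything.
`viromine` implements the desk-scale analysis toolkit for the strategy
of leveraging a few sequenced reference phages (here, five cyanophages
infecting *Pseudanabaena mucicola*) to mine a shotgun virome:

* **Read recruitment (RBB).** Reference proteins recruit reads by
  translated search (E ≤ 10⁻³); each candidate read is then searched
  against reference **plus decoy** proteomes and is assigned to phage
  *i* only if its single best reciprocal hit belongs to phage *i*.
  Relative abundance is genome-length-normalized:
  `fraction_i = (n_i/L_i) / Σ_j (n_j/L_j)`.
* **Contig mining.** Assembled contigs are kept in the 10–200 kb
  tailed-phage band, circular genomes are recognized by their terminal
  direct repeat (longest exact prefix/suffix match ≥ 20 bp) and
  trimmed, and every contig is placed against a reference panel with a
  normalized genome similarity score
  `SG(A,B) = 2·S(A,B) / (S(A,A)+S(B,B)) ∈ [0,1]` (S = summed bitscores
  of non-overlapping translated HSPs), then clustered by UPGMA on
  `1 − SG`.
* **CRISPR host linkage.** A simplified repeat–spacer detector finds
  arrays in a host genome and matches each spacer against phage
  genomes (ungapped, both strands, ≤ 2 mismatches) to find
  protospacers — evidence of past infection.
* **Synthetic data.** Every input can be generated with known ground
  truth: circular genomes with planted ORFs, reads at spiked
  abundances with substitution errors, decoys, terminal-repeat
  contigs, and CRISPR-bearing hosts.

The translated alignment engine (BLOSUM62, gaps 11/1, Karlin–Altschul
E-values, numba-compiled kernels) is part of the package; any search
stage can alternatively be fed a standard 12-column tabular hit file
from an external aligner. Full model details and assumptions are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate the five-phage community at the published genome lengths
(36,043 / 142,856 / 54,544 / 48,349 / 39,509 bp), spiked at
48.7 / 8.9 / 3.1 / 5.2 / 34.1 % for pam1..pam5, with 50,000 reads, 1%
substitution errors and 20% decoy reads — then recruit and recover the
abundances:

```bash
python analysis/01_simulate_community.py --seed 11
python analysis/02_recruit_abundance.py  --seed 11
```

prints

```
reads: 50000  assigned: 30749  unassigned: 19251  ambiguous: 0
phage  read_count  percent  spiked_percent  abs_error
 pam1     11208.0     48.5            48.7        0.2
 pam2      8144.0      8.9             8.9        0.0
 pam3      1093.0      3.1             3.1        0.0
 pam4      1642.0      5.3             5.2        0.1
 pam5      8662.0     34.2            34.1        0.1
mis-assigned reads: 2; max abundance error 0.20 points
```

Reading this: about 61% of reads end up assigned — the rest are decoy
reads correctly rejected by the reciprocal stage plus reads from
non-coding regions, which protein-space recruitment cannot see. Raw
read counts do **not** match the spiked percentages (pam2's genome is
4× longer than pam1's, so it yields 4× the reads per genome copy);
after genome-length normalization every phage's abundance is recovered
within 0.2 points. Only 2 of ~30,000 assigned reads land on the wrong
phage.

The other drivers exercise the remaining stages and write their
tables under `results/`:

```bash
python analysis/03_mine_contigs.py    # band filter, circularization, SG, tree
python analysis/04_crispr_match.py    # array detection + protospacer report
```

The same stages are available as a CLI for external data
(`viromine simulate|recruit|mine|sg|tree|crispr`, see
`viromine --help`); every run drops a `manifest.json` with the config
echo, input checksums and seed, and reruns are byte-identical.

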