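# Methods

`viromine` implements a reference-guided mining workflow for viral
metagenomes: given a handful of sequenced phage genomes (here, five
freshwater cyanophages infecting *Pseudanabaena mucicola*), it
(1) recruits shotgun virome reads to those references and converts the
counts into genome-length-normalized relative abundances, (2) triages
assembled contigs into candidate ("virtual") phage genomes, and
(3) links phages to hosts through CRISPR spacer/protospacer matches.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data experiments do and do not show.

## Reciprocal best-hit (RBB) read recruitment

Recruitment is performed in protein space, not by nucleotide mapping:
viral reads diverge quickly at the DNA level while protein-level
homology persists.

*Forward pass.* Every reference protein is searched against the read
set as a translated (tblastn-style) query with E ≤ 10⁻³. The union of
hit reads per reference phage forms the candidate set.

*Reciprocal pass.* Each candidate read is searched in all six frames
against the combined database of reference proteomes **plus a decoy
proteome** of unrelated tailed phages, keeping only the single best
target. A read is assigned to phage *i* iff that best hit is a protein
of phage *i*. A best hit in a decoy leaves the read unassigned; a raw
bitscore tie spanning a decoy and a reference, or two distinct
references, marks it ambiguous. Reads are counted once each,
regardless of how many proteins they hit, which avoids gene-length
double counting. Ambiguous reads are dropped from abundance by default
(`tie_policy="drop"`); the `"split"` policy shares them equally among
tied reference phages.

*Abundance.* With nᵢ assigned reads and genome length Lᵢ,

    fraction_i = (n_i / L_i) / Σ_j (n_j / L_j).

Normalizing read counts by genome length converts read share into
genome-copy share: a phage twice as long yields twice the reads per
genome copy. The alternative normalization (read fraction divided by
length fraction) is algebraically identical up to a constant.

*Paired ends.* Mates are treated as independent reads; the recruitment
logic never uses pairing information.

## The alignment engine

All searches share one scoring system: BLOSUM62, affine gaps 11/1,
Karlin–Altschul E-values with hard-coded (λ, K) — gapped (0.267,
0.041) and ungapped (0.3176, 0.134) — and the standard logarithmic
length adjustment on the effective search space
`(m − l)(N − n_seq·l)`. These statistics are an approximation of what
a production aligner computes (which fits its parameters at runtime);
they are used only to threshold and rank hits, and the default cutoff
E ≤ 10⁻³ matches the reference analysis. Low-complexity filtering is
off, matching the stated search configuration.

Two execution paths share the kernels (numba-compiled):

* **Per-query gapped path** (`search_protein_vs_dna`,
  `search_dna_vs_protein`): seeds are word-window scores over the
  substitution profile (word 3, neighborhood threshold 11 — so
  neighborhood words are included by construction), and every seeded
  frame is resolved by a *full* affine-gap Smith–Waterman with
  traceback when the DP area is ≤ 4·10⁶ cells (diagonal windows of
  ±16 around seed clusters otherwise). Running the exact DP on seeded
  frames is what makes the engine's top score provably equal to an
  exhaustive per-frame dynamic program at desk scale — a property the
  test suite checks against an independent aligner
  (Bio.Align.PairwiseAligner) on random pairs.
* **Batch ungapped path** (`batch_search_reads`,
  `translated_genome_hsps`): exact amino-acid word index (word 4 for
  read recruitment — longer than the per-query default purely for
  index selectivity at 50,000-read scale) followed by X-drop ungapped
  extension (X = 16–20) with per-diagonal seed deduplication.
  Ungapped HSPs are the appropriate model here: the all-frames
  genome-vs-genome search mirrors tblastx, which is ungapped, and the
  recruitment substrate is high-identity reads whose substitution
  errors never shift the reading frame.

Tie-breaking is bitscore descending, then E-value ascending, then
subject id lexicographic, everywhere, so all outputs are
deterministic.

## SG: normalized genome similarity

The reference analyses place genomes on a proteomic tree via an
external server whose exact score is not published. `viromine` uses a
symmetric, self-normalized variant with the same intent:

    S(A,B)  = Σ bitscores of E-filtered tblastx-like HSPs,
              greedily selected by descending score subject to
              non-overlap of their genome-A nucleotide intervals
    SG(A,B) = 2·S(A,B) / (S(A,A) + S(B,B)),  clipped to [0, 1]

SG(A,A) = 1 exactly by construction, and the pair score is computed
once in a canonical (lexicographic) orientation so SG is symmetric to
the last bit. Greedy interval selection on nucleotide coordinates
(rather than exact weighted-interval scheduling) is a deliberate
simplicity/determinism trade, oracle-tested on small cases. The
familiar threshold vocabulary (SG < 0.05 distant, 0.05–0.1 related,
0.1–0.5 close, floor 0.005) is kept as configuration constants but is
approximate under this re-definition — the published thresholds
calibrate a different formula.

Dendrograms are UPGMA (average linkage, scipy) on distance 1 − SG with
taxa pre-sorted lexicographically for deterministic tie-breaks;
branch lengths are ultrametric (leaf-to-node height = half the merge
distance).

## Contig mining

* **Length band**: 10–200 kb inclusive, applied to the *untrimmed*
  contig (the band the reference analysis applied before any further
  processing; whether it preceded trimming there is unstated — we
  filter first).
* **Circularization**: the longest exact prefix/suffix match (KMP
  border, O(n)); ≥ 20 bp calls the contig circular and trims the
  duplicated copy, so re-appending the overlap reproduces the input
  byte-for-byte. Exact matching mirrors assembler k-mer overlap
  behaviour; no mismatch tolerance by default.
* **External phage classification** (e.g. VirSorter2) is consumed as a
  (contig_id, score) TSV and used only as an optional ≥ 0.5 filter —
  it is never re-implemented.
* **Verdict**: a contig is a "virtual cyanophage" iff its
  nearest-by-SG reference is a cyanophage and SG ≥ 0.005.

## CRISPR arrays and protospacers

The scientific step is spacer → protospacer matching; array *calling*
is intentionally simplified plumbing (spacers can be supplied as FASTA
to bypass it). The detector anchors on exact 16-mers recurring ≥ 3
times with spacing in [repeat+spacer] band (repeats 23–55 bp, spacers
20–60 bp), grows repeat boundaries while every copy stays within 1
mismatch of the column consensus, and resolves overlapping candidates
longest-first. Boundary growth additionally requires each new column
to be consensus-dominated (at most `max(1, n_copies // 4)` disagreeing
copies): with ≥ 3 identical repeats a purely per-copy budget lets one
random column beyond the true boundary slip in, shifting all
spacer boundaries by a base. Tandem repeats with zero-length gaps are
rejected by the spacer band.

Matching is ungapped, both strands, Hamming distance ≤ 2 by default —
enough to cover the exact and single-mismatch (38 bp) protospacers
reported for this phage/host pair — with circular subjects scanned
across the origin. Coordinates are 1-based inclusive on the forward
strand, matching the printed coordinate style. N matches nothing.

## Synthetic data: what it emulates and what it does not

`simulate` generates every input with known truth, at the study
conditions by default:

| parameter | default | why |
|---|---|---|
| genome lengths | 36,043 / 142,856 / 54,544 / 48,349 / 39,509 bp | the five published reference genomes |
| spiked abundances | 48.7 / 8.9 / 3.1 / 5.2 / 34.1 % (pam1..pam5) | the published October-2017 estimate |
| G+C | 0.35 (0.736 for pam4) | published genomic means |
| reads | 50,000 × 150 nt, substitution rate 0.01 | short-read virome at a desk-scale depth |
| decoy fraction | 0.20 of reads, 3 unrelated 40-kb genomes | exercises the reciprocal rejection stage |
| coding density | 0.70, pinned exactly per genome | equalizes per-read recruitment probability across phages (a realized-coding-fraction difference of a few % would bias abundance by more than the recovery tolerance) |
| gene length | uniform 100–400 codons | typical phage ORF range |

Reads are drawn with weights ∝ abundance × genome length, so
"abundance" means genome-copy fraction and the length-normalized
estimator is unbiased for the spiked vector. Genomes are circular;
reads wrap the origin. Each planted ORF is preceded by an in-frame
stop so it is *maximal*, and unplanned maximal ORFs ≥ 100 aa are
disrupted by synonymous (in-gene) or direct (intergenic) stop-codon
edits — the ORF scanner therefore recovers exactly the planted genes,
which gives the generator a sharp, testable contract. All generators
are deterministic under a fixed seed, with independent per-generator
RNG streams (`SeedSequence` spawn keys; plain composite seeds can
collide through zero padding).

Not emulated: indels and platform error profiles (the recruitment is
protein-space and the error model substitution-only), quality-score
structure, paired-end inserts, real phage gene content (synthetic
proteins are random-codon, so database-wide homology structure — e.g.
conserved terminase families shared between references and decoys —
is absent). Passing the synthetic experiments therefore demonstrates
the *machinery* (assignment logic, normalization, detection,
trimming, clustering) under controlled truth; it does not measure
sensitivity on real, distantly homologous viromes, where the decoy
database's composition dominates the reciprocal stage.

## Problem sizes in the shipped experiments

The test-suite and acceptance experiments use the full 50,000-read
community (five read seeds for the recovery check), 100 contigs for
circularization, 12 genomes of 12 kb in 3 clades for the dendrogram,
20-kb pairs for the SG negative control, and a 100-kb host for CRISPR
detection. The oracle-equality check runs 20 random protein/DNA pairs
at ≤ 200 aa × ≤ 1,000 nt, where full-DP resolution is guaranteed.

## Known limitations

* E-values are approximate (fixed λ, K; simplified length
  adjustment); they are thresholds, not calibrated probabilities.
* SG threshold semantics are approximate relative to the published
  tree server (formula not printed there).
* The per-query gapped search reports one best local alignment per
  seeded frame/window rather than all HSPs.
* The CRISPR detector is a consensus-repeat finder, not a published
  annotation tool; degenerate repeats beyond 1 mismatch per copy, or
  arrays with < 3 units, are out of reach by design.
* Comparison against the deposited genomes (GenBank
  ON014753–ON014757) and the archived virome run requires downloading
  those data; the corresponding check stays red until they are placed
  under `data/references/`.
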