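# Methods

This note documents the models, parameter choices and numerical
conventions behind famscan, and what the synthetic dataset does and
does not emulate.

## Family identification

A profile-HMM search is the field's standard first step for gene-family
identification. famscan replaces it with a transparent equivalent built
from the family's published consensus motifs: for each motif the best
window on a protein is found by exhaustive sliding (leftmost window on
ties), where a window position matches if the residue equals the
consensus letter or falls in its ambiguity class (B = D/N, Z = E/Q,
J = I/L, X = any). The family score is the mean best fraction over the
core motifs {1, 3, 4}, which every true member carries.

Significance is empirical: `n_shuffles` (default 999) residue-permuted
proteins are drawn round-robin from the query proteome and scored with
the same statistic; the E-value of a score *s* is
`N_db · (1 + #{null ≥ s}) / (1 + n_shuffles)`. This estimator is
conservative (the +1 terms make it a valid permutation p-value scaled
by database size) and has a floor of `N_db/(n_shuffles+1)` — about
0.055 for the default 55-protein proteome. A profile-search cutoff of
1e-5 is therefore unreachable on this scale; the default acceptance
threshold is **E < 0.1**, which requires a candidate to outscore every
null replicate. The threshold, presence cutoff (best fraction ≥ 0.8)
and shuffle count are all configurable.

Filters: *redundant* means byte-identical sequence to an
already-accepted candidate or ≥ 50 % locus overlap with one (the
higher-scoring candidate wins; ties go to the lexicographically smaller
id — this makes acceptance order-invariant); *incomplete* means any
core motif below the presence cutoff. "Redundancy" is not defined
operationally in the literature this models; the 50 % locus-overlap
rule is this package's operationalization and is recorded in the
output metadata.

## Protein properties

ORF length is 3·(aa+1) bp: one codon per residue plus the stop codon —
the relation holds exactly for every row of the curated family table.
Molecular weight sums average (not monoisotopic) residue masses plus
one water (18.0153 Da), matching the ProtParam convention. The
isoelectric point bisects the Henderson–Hasselbalch net charge
(N-terminus, C-terminus, and D/E/C/Y/H/K/R side chains) on pH ∈ [0, 14]
to |charge| < 1e-4 or interval < 1e-3, with the Bjellqvist pKa set
including ProtParam's terminal-residue refinements (e.g. an N-terminal
Ala shifts the terminal pKa to 7.59). Alternative pKa tables are
injectable; passing explicit tables bypasses the terminal refinements.

## Phylogeny

The reference workflow aligns all sequences at once and computes
distances with pairwise gap deletion. famscan computes distances from
**pairwise global alignments** (BLOSUM62, gap open 10, extend 0.5)
instead of re-implementing progressive multiple alignment — a
documented deviation. For each pair, alignment columns containing a gap
are deleted; p = mismatches / compared columns; the Poisson option maps
p to −ln(1−p) (undefined at p = 1, which raises). Neighbor joining is
the standard Saitou–Nei agglomeration with Studier–Keppler updates;
ties in Q are broken by the lexicographically smallest (min-leaf,
max-leaf) pair of the candidate nodes, making the tree invariant to
input order. Negative branch-length estimates are clamped to zero with
the deficit moved to the sibling branch (the MEGA convention).

The bootstrap resamples each pair's gap-deleted columns with
replacement, all pairs drawing from one seeded generator per replicate;
support is 100 × the fraction of replicate trees containing the edge's
bipartition. Because columns are resampled per pair rather than from a
shared alignment, supports are approximate in the same sense the
distances are; `resample=False` is a determinism check (every original
edge gets 100).

Subfamilies are extracted by deleting the k−1 longest internal edges
(ties by higher support, then bipartition label) — the package's
operationalization of "visual clades". If k approaches the leaf count,
terminal edges are cut longest-first until k leaf groups exist. Groups
are labelled A, B, … by decreasing size, ties by smallest member id.
Sister pairs are terminal cherries whose Smith–Waterman identity
reaches `identity_min` (default 0.95 — sister pairs in this design are
recent duplicates with ≥ 96 % identity, and the threshold suppresses
occasional spurious cherries produced when NJ mis-resolves two adjacent
short internal edges).

## Duplication classes

Local alignment is an affine-gap Smith–Waterman (scores floored at 0,
traceback from the maximum cell; ties toward smaller row then column;
first gap residue costs the open penalty). Defaults BLOSUM62, 10/0.5
match the EMBOSS `water` tool. Classification: *tandem* requires the
same chromosome, start-to-start distance ≤ 100 kb and ≤ 5 annotated
genes strictly between; *segmental* is assigned to
different-chromosome coparalogs — a documented simplification of
duplicated-block detection, with an injectable block list
(`segmental_blocks`) for users who have one. Same-chromosome pairs
failing the tandem rule are *ambiguous*.

## Expression and qPCR

Normalization divides every FPKM value (plus pseudocount, default 0.01
to guard log2(0)) by the grand mean of the matrix and takes log2, so
the mean pre-log ratio is exactly 1. Gene clustering is UPGMA on
Euclidean row distances via scipy. "Expressed" means FPKM ≥ 1 by
default (the qualitative published threshold made concrete);
configurable.

ΔCT averages technical replicates before subtracting the reference CT;
ΔΔCT compares treated and control means; calls require both a
significant equal-variance Student's t-test on biological-replicate
ΔCTs (α = 0.05; Welch available) and a fold change ≥ 2 (or ≤ 0.5).
The 2-fold gate is this package's default — the source protocol states
only p < 0.05 — and `fold_min=1` reproduces significance-only calling.
No multiple-testing correction is applied by default, matching the
protocol. Biotic-treatment comparisons flow through the same call
logic.

## The synthetic dataset

The generator plants exactly the structure the analyses are meant to
recover, from one seed:

* **Scaffold**: one resolved instance of each of the ten motifs
  (ambiguity letters drawn uniformly), ordered N-terminal ATPase motifs
  first (7, 9, 1, 4, 2, 3) then substrate-binding/lid motifs
  (5, 10, 6, 8) — the published numbering is not positional, so the
  NBD→SBD→lid order is a design choice, configurable. Linkers of
  8–18 random residues join the motifs.
* **Evolution**: members diverge along a fixed five-subfamily topology
  (sizes 10/3/3/1/3) by i.i.d. per-site substitutions. Branch classes:
  terminal 0.05 substitutions/site, sister-pair leaves 0.02 (recent
  duplicates), caterpillar spine edges 0.09, subfamily stems 0.25
  (0.6 for the largest subfamily, whose internal depth would otherwise
  mask its stem under p-distance saturation), backbone 0.083. Motif
  segments evolve at 12 % of the branch rate (4 % for the core motifs):
  conserved domains vs spacers. The large subfamily is a caterpillar
  with its two cherries at the ends, so the family's only cherries are
  the five planted sister pairs. Motif losses are planted per the
  published pattern (member 6 lacks motif 7, member 14 lacks motif 8,
  the long subfamily lacks motifs 2/5/10, etc.). Lengths are matched
  exactly to the published per-member values by growing a shared
  C-terminal tail at each subfamily ancestor and trimming each leaf
  (linker edits only — no general indel model).
* **Genome**: the 20 genes sit at the published chromosome:kb spans
  (kb × 1000, 1-based, plus strand), with the published intron counts;
  the narrative reading (members 10 and 11 intron-less) is the default
  and `table_intron_counts=True` restores the printed column. Introns
  are 100–500 bp placed uniformly inside the CDS; leftover span is 3'
  UTR. CDSs are random-codon reverse translations of the proteins, so
  translation round-trips exactly. Decoys: two duplicate isoform
  records sharing a member's locus (redundant) and three fragments with
  a core motif excised (incomplete); 30 random background genes, three
  of them placed inside the tandem windows so the intervening-gene rule
  is exercised.
* **Expression**: pattern classes (broad / silent / root+tuber /
  root+tuber+stolon / all-but-stamen / vegetative) set per-gene means
  (high 100, low 0.2 FPKM) with multiplicative log-normal noise
  (σ = 0.25); zero means stay exactly zero.
* **CT tables**: reference CT 20 in expectation; per-gene target
  baselines 22–26; planted effects shift treated CT by ∓2 cycles
  (4-fold) for up/down genes; Gaussian biological (σ = 0.2) and
  technical (σ = 0.1) noise; 3 biological × 3 technical replicates.

What it does **not** emulate: realistic nucleotide composition or codon
usage, indel evolution beyond linker edits, correlated expression
noise, primer efficiencies, or genome-scale background gene density.
Passing tests therefore demonstrate the correctness and calibration of
the analysis chain under a controlled data-generating process, not
performance on real proteomes.

## Determinism and seeds

Every stage derives its own generator from the top-level seed via
`derive_seed(seed, stage)` (a CRC-mixed affine map), so toggling one
stage never shifts another's random stream; identical configurations
produce byte-identical FASTA/GFF3/TSV outputs.

## Problem sizes used in tests

The default dataset is 55 proteins (~200–900 aa). The test suite runs
the full identification (999 shuffles), a 100-replicate bootstrap on
the 20 members, a 2000-unit null simulation for t-test calibration, and
brute-force alignment enumeration on ≤ 5-residue pairs; the complete
suite takes well under a minute on one CPU.

## Known limitations

* The permutation E-value scale depends on the shuffle count; cross-run
  comparability requires fixing `n_shuffles`.
* Bootstrap supports inherit the pairwise-alignment approximation; on
  real data a progressive MSA upstream would be preferable.
* Segmental calls without a block list are a chromosome-disjointness
  heuristic, not synteny detection.
* Under strong saturation, p-distance NJ can shorten deep stems; the
  Poisson option mitigates but does not remove this.
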