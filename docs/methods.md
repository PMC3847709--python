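# Methods

This note documents the models, defaults and numerical choices behind
`venomscan`, and what the synthetic benchmark does and does not demonstrate.

## The synthetic transcriptome

The generator emulates the statistical shape of a snake venom-gland cDNA
experiment rather than any particular dataset. The default library plants,
on top of 200 housekeeping and 5 transposon-like background transcripts:

| family | n | structure |
|---|---|---|
| three-finger toxin (3FTx) | 13 | 62-aa mature chain, ten cysteines at fixed scaffold positions; isoforms drawn from 4 similarity clusters (~90% within-cluster protein identity) plus one divergent outlier |
| sarafotoxin (SRTX) | 2 | polycistronic precursor: signal peptide + 3 tandem cassettes, each `spacer–KR–(21-aa endothelin-like core)–DEP`; the excised long-form mature peptide is 24 aa |
| lipocalin | 3 | 150-aa mature, 4 cysteines |
| CRISP | 1 | 200-aa mature, 16 cysteines |
| novel secreted | 10 | 173-aa mature region with two conserved cysteines — the "unannotated most-abundant transcript" scenario |
| non-secreted orphan | 1 | highly transcribed, cysteine-bearing, **no** signal peptide: negative control for the novel screen |

Each CDS is produced by back-translation with uniform synonymous codon usage,
flanked by short UTRs (the 5' UTR is ATG-free so the annotated start is the
longest ORF's start). Because isoforms are mutated at the protein level and
back-translated independently, nucleotide identity between isoforms stays
well below the assembler's 98% threshold, so distinct isoforms do not
co-assemble.

**Signal peptides.** Secreted templates start with a 20-residue generated
signal (`M` + K/R + 14 hydrophobic residues + `NAPA`), designed to be accepted
by the package's own predictor with cleavage exactly after residue 19.
Generator/detector consistency is asserted at generation time, which is what
makes recovery rates of downstream stages interpretable.

**Abundance.** Weights follow a discrete truncated power law over a planned
rank order (the most abundant transcript is a novel secreted isoform, the
orphan control sits at rank 2, lipocalins at 3–5, the remaining planted
families interleaved through the high-abundance band, sarafotoxins planted
low). The exponent is fitted by bisection at generation time so the expected
share of the 57 highest-weight templates is 0.55 — chosen once to sit clearly
above one-half, the qualitative property the pipeline's abundance gate relies
on. Non-normalized libraries sample reads multinomially from these weights;
normalized libraries sample from `w^γ` with γ = 0.25, a free stand-in for
duplex-specific normalization kinetics, which are not modelled mechanistically.

**Reads.** Lengths are normal (mean 315 nt non-normalized / 344 normalized,
sd 50), truncated to [50, transcript length]; start positions uniform; both
strands sampled; substitution errors at 0.5% by default (range [0, 5%]).
Homopolymer indels, chimeras and quality-value error profiles are *not*
modelled. Consequently, passing recovery tests demonstrates the logic of the
pipeline under substitution noise and heavy-tailed abundance — not robustness
to indel-rich chemistry or to real cross-contamination artefacts.

**Reference panel.** A curated-database stand-in is derived from the planted
toxin templates: one homolog per toxin isoform at ~18% protein divergence
(cysteines conserved) with family keywords in the description line, plus ten
decoy entries from unrelated toxin families. Deriving one panel homolog per
isoform makes reciprocal-best-hit confirmation attainable for every planted
toxin, mimicking a well-populated database.

## Assembly

Greedy overlap-consensus: seed with the longest unassigned read, repeatedly
join the unassigned read with the largest passing overlap (ties by read id),
thresholds ≥ 40 bp overlap and ≥ 98% identity. Candidate overlaps are found
with a sampled k-mer index (k = 16, stride 12) over both strands and verified
as exact ungapped overlaps at the k-mer diagonal; reads whose best placement
is on the reverse strand are reverse-complemented before joining. The
ungapped overlap model is exact for substitution-only reads (the simulator's
error model) and is what makes the 100,000-read benchmark tractable; it will
under-join indel-rich data, which is out of scope. Consensus is per-column
majority with ties resolved toward the earliest-joined read's base. Reads
shorter than 50 nt are never assembled and are reported among the singletons
(with a logged count), so contig membership plus singletons always partition
the input reads. Detection sensitivity drops for overlaps whose every sampled
k-mer contains a mismatch; at the default error rate this affects well under
1% of joins.

## ORFs and the signal-peptide heuristic

ORFs run from ATG to an in-frame stop (both required; partial ORFs at contig
ends can be requested and are flagged truncated, feeding the stringency
filter), translated with the standard code, minimum 60 aa, reported longest
first. The signal-peptide call is a deterministic rule set in the von Heijne
spirit: ≥ 1 K/R among the first 5 residues; a ≥ 6-residue window with mean
Kyte–Doolittle hydropathy ≥ 1.6 within residues 3..c−4; small residues
(A/G/S/C/T) at c−3 and c−1; cleavage position c in [15, 35], chosen to
maximise the window score (ties to the smallest c). All thresholds live in
`SignalParams`. On shuffled mature-region sequences the false-positive rate
is ~2–3%. This is a heuristic stand-in for an HMM/ANN predictor: adequate for
co-designed synthetic data, not validated on real proteomes.

## Similarity statistics

Alignments are exact local Smith–Waterman with BLOSUM62 and affine gaps
costing `11 + L` for a gap of length L; ambiguous residues (X) score 0.
E-values use the Karlin–Altschul form with the standard gapped BLOSUM62-11-1
constants λ = 0.267, K = 0.041 (configurable), with `n` equal to the panel's
total residue count to approximate database-mode statistics. No edge
correction, compositional adjustment or HSP chaining is applied, so E-values
are indicative rather than BLAST-identical; all decision thresholds (1e−5,
1e−10, 1e−20) were chosen on this internal scale. Reciprocal best hits
exploit score symmetry (one score matrix, tops taken in both directions;
score ties disqualify a pair and are logged). Non-redundant clustering is
greedy longest-first with identity measured over the shorter sequence.

## Annotation decisions

Verdicts are exhaustive and exclusive per transcript: `known_toxin`
(keyword + RBH), `excluded` (truncated / ambiguous positions / no signal
peptide — with named relaxation for weakly expressed families, sarafotoxins
by default), `novel_candidate` (no panel hit ≤ 1e−5, signal peptide, ≥ 2
mature cysteines, abundance rank ≤ 57), else `non_toxin`. Abundance is raw
mapped-read counts — not length-normalized — because the screen ranks
transcripts by read share; ranks are dense with ties broken by id for
display. Each contig is represented by its longest complete ORF (longest
partial as fallback). The sarafotoxin parser excises cassettes at a
configurable motif (dibasic `KR` boundary, 21-residue `C-x-C...` core,
optional `DEP` extension); real propeptide processing sites are more complex
and are not claimed.

## Selection screen

NG86 with equal-weight pathway averaging for multi-hit codons and
Jukes–Cantor correction. Mutations to stop codons count as nonsynonymous
sites (conserving 3 sites per codon); pathways through stops are excluded
from difference averaging unless all pathways pass through one. Saturated
corrections (log argument ≤ 0) are flagged and excluded from group means; a
group is "diversifying" when the mean pairwise ω over defined pairs exceeds
1. The bundled codon simulator evolves sequences from a random ancestor by
accept/reject single-nucleotide proposals (synonymous accepted with
min(1, 1/ω), nonsynonymous with min(1, ω)), which realises the target dN/dS
up to a small downward bias at high ω (stop-adjacent proposals are rejected
but counted as nonsynonymous sites by the estimator); recovery is within 20%
for ω in [0.2, 3] at the benchmark divergences. This is a counting screen:
it preserves the inferential *direction* of ML site models (ω > 1 ⇒
diversifying) but estimates no site-specific effects.

## Problem sizes and determinism

All stochastic components take explicit seeds and are bit-reproducible for a
fixed seed. The benchmark scale used throughout the tests and the acceptance
script is the default library (235 templates) with 100,000 reads — large
enough that the top-57 read share and per-family recovery rates are stable
across seeds (the top-57 share varies by ~±0.3 percentage points), while the
whole suite runs in minutes on one CPU. The normalized-vs-non-normalized
comparison ("transcripts needed to reach 80% of reads") is computed on reads
mapped to the transcript references for both libraries, which isolates the
abundance-distribution effect the comparison is about.

## Known limitations

- No homopolymer/indel error model; the assembler's ungapped overlap
  verification inherits that assumption.
- E-values are internally calibrated, not NCBI-BLAST-compatible.
- The signal-peptide rule set and the cassette motif are transparent
  heuristics, tuned for the co-designed generator, not for real proteomes.
- The dN/dS screen is pairwise counting only: no tree, no site models, no
  branch-site inference.
- The reference panel stands in for a curated toxin database; family
  annotation quality on real data depends entirely on the panel supplied.
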