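# Methods

## Gene models and exon grouping

Gene structures come from GTF exon records (1-based inclusive
coordinates) plus a genome FASTA. Exons overlapping by ≥ 1 bp are merged
into *exon groups* — the connected components of the pairwise overlap
graph; intervals that merely touch remain separate groups. Groups are
serial-numbered in transcription order, so on the minus strand group 1
is the interval set with the highest genomic coordinates, and all
sequence extraction reverse-complements minus-strand intervals. Introns
are the gaps between consecutive group spans; a zero-length gap
(book-ended groups) produces no intron, and intron *i* always sits
between groups *i* and *i*+1. Transcript proteins are taken from a
protein FASTA when supplied; otherwise the spliced exon chain is
translated at the annotated phase of its 5'-most exon, or, absent phase
annotation, at the longest stop-free forward frame.

## Junction peptide database

For a gene with G groups the candidate set is: G exon peptides, C(G,2)
exon–exon junctions (G−1 *normal* adjacent pairs, the rest *skipping*),
and one exon–intron plus one intron–exon junction per intron. Junction
windows take up to 210 nt from the end of the left segment and 210 nt
from the start of the right segment — 3·140/2 per side, so each of the
three reading frames can reach the 140-residue cap, chosen because no
single MS/MS spectrum yields a longer peptide fragment. Exon peptides
are not capped (they represent whole exon-group regions, not spectral
matches).

Each junction window is translated in all three frames
(standard genetic code; codons with non-ACGT characters render `X`,
stops `*`). The junction offset is the first residue whose codon
contains a base of the right segment; a frame whose offset falls outside
`[1, len−1]` cannot span the junction and is dropped. Stop-codon
validation then distinguishes types:

* exon, knowledge-based exon–exon, and intron–exon candidates are
  discarded on **any** stop;
* theoretical exon–exon and exon–intron candidates are discarded when a
  stop precedes the junction; a stop at or past the junction truncates
  the peptide, which is kept only if it still spans the junction.

The intron–exon rule is deliberately strict (a stop anywhere, even in
the intron portion, discards), mirroring the asymmetry of the rule set:
for left-retention evidence the intron portion is the putative coding
extension and must be open.

A peptide is labeled `_KB` iff its full sequence is a substring of a
transcript protein *of the same gene*, `_TH` otherwise; exon–intron and
intron–exon junctions are by construction always theoretical, and exon
peptides are reported under the single `EXON_KB` category. Exon
candidates without phase annotation emit one peptide — the longest
stop-free frame — rather than three frame variants; three frames of the
same genomic exon are redundant evidence for the *same* region (unlike
junctions, where the frame changes which fusion peptide is predicted),
and one canonical translation keeps the exon category in one-to-one
correspondence with exon groups. Candidates are de-duplicated by
(gene, type, serials, frame); identical sequences arising from different
junctions are kept as distinct evidence. FASTA headers are
`gene|category|left-right|Fframe` with the junction offset appended as a
description field, so a written database round-trips.

## Marker screening

Intensities (peptides × samples, missing allowed) are log2-transformed
and quantile-normalized: each sample's observed values are replaced by
the cross-sample mean order statistics at matching quantiles
(interpolated on a common grid when samples differ in missingness).
Presence is called per cell as *observed and ≥ threshold*; the default
threshold is the 5th percentile of all observed normalized intensities.
The underlying notion is a quality floor — an intensity too low to trust
does not count as an identification — so missing cells are absent and
values at the threshold are present.

Each peptide's 2×2 table (present/absent × health/cancer) is tested with
the Pearson chi-square statistic, df = 1, no continuity correction;
degenerate margins return (χ²=0, p=1). No per-peptide correction is used
because the uncorrected statistic is the one whose closed form
n(ad−bc)²/(R₁R₂C₁C₂) the screen's count data follow; the separate
`contingency_chisq` helper exposes a Yates flag for marker-class
summary tables, where the corrected statistic is conventional for small
cells. Benjamini–Hochberg adjusted p-values come from statsmodels.
Storey–Tibshirani q-values use π0(λ) = #{p>λ}/(m(1−λ)) on
λ = 0.05…0.95 (step 0.05) with a cubic polynomial trend evaluated at
λ = 0.95, clamped to (0, 1]; for m < 100 the raw λ = 0.5 estimate is
used (a smoothed extrapolation is unstable on so few points). Markers
are declared at q < α (default 0.05), and the expected number of false
positives is α × #declared.

Calibration note: the 2×2 chi-square is discrete, so its exact size at
the simulator's null (presence 0.5, 40 vs 40) is 0.0567 rather than
0.050 — computed by exact binomial enumeration and asserted in the test
suite; empirical null fractions are compared against that exact size
within binomial tolerance.

## Explainable Index

Per gene, declared markers are assigned to the health set H or cancer
set C by the group with the higher presence proportion, and interpreted
as single-exon markers E_j or junction markers E_iE_k (i < k; exon–
intron/intron–exon markers carry no exon-pair reading and are skipped).
A marker is *consistent* when (1) it participates in a pair E_j ∈ H,
E_iE_k ∈ C with i < j < k; (2) it is an E_j ∈ H with no junction
spanning j; or (3) it is an E_iE_k ∈ C with no single-exon marker
strictly inside (i, k). The *inconsistent* conditions mirror these with
H and C exchanged. α = ((#con_C+1)/(#inc_C+1))·((#con_H+1)/(#inc_H+1));
α > 1 labels the gene "more explainable". Two open points are resolved
explicitly and exposed as switches: the negations in conditions 2/3
quantify over **both** marker sets by default (`scope="opposite"`
restricts them to the set condition 1 names), and a two-marker condition
credits **both** participants, each toward its own set's counter. A
marker satisfying conditions on both sides (possible only with
overlapping set membership) counts once per side by default
(`policy="consistent_wins"` available).

## Panel selection

Samples are encoded as binary presence vectors over the candidate
markers with the two-node outcome coding cancer = (1,0),
healthy = (0,1). The classifier is a fixed N-7-2 network, sigmoid
activations on both layers, trained by full-batch gradient descent with
momentum (lr 0.5, momentum 0.9) on the summed two-output cross-entropy.
`train` runs 500 epochs and keeps the best of 5 random initializations
by training loss; `select_panel` trains one network per combination with
60 epochs and a single initialization — on binary presence inputs of
this size the loss is converged well before that, and the search only
needs score *rankings*. All networks of a search batch train
simultaneously via a batch axis over the weight tensors (float32 for
large batches), which is what makes exhaustive C(26,5) enumeration
cheap. Combinations are ranked by Mann–Whitney AUC
(P(score_c > score_h) + ½P(equal), tie-corrected via average ranks) of
the cancer-node score on the independent test cohort, and the
AUC-maximizing combination is returned; an `objective="min"` switch
exists for completeness. Hard labels decode by argmax of the two output
nodes with exact ties resolved to healthy (the conservative direction).
Selecting on the test cohort leaks information into panel choice — the
default mirrors the study design this models, but training-cohort
validation splits are straightforwardly obtained by passing a held-out
`test_ds` drawn from the training cohort.

## Synthetic data

`make_toy_genome` emits genes of 2–5 exon groups (alternating strands)
whose exon and intron segments are built from uniformly sampled *sense*
codons with lengths a multiple of 3. Consequently frame 0 is stop-free
in every segment and aligned across segment boundaries, which guarantees
the annotated transcript (all group spans, phase 0) yields a stop-free
protein, normal exon–exon junction peptides in frame 0 are substrings of
it (`_KB`), and every one of the five database categories is populated;
the other frames and the skip/retention junctions exercise the
theoretical and stop-discard paths. This is deliberately idealized: real
introns are rich in stops, codon usage is non-uniform, and splice sites
have sequence motifs — none of which the generator models, so passing
tests demonstrate the bookkeeping and statistics, not biological realism
of the sequences.

`simulate_study` mirrors a 40-vs-40 plasma design: planted peptides are
present with probability 0.9 in cancer and 0.1 in health (nulls: 0.5 in
both); present cells draw log2 intensities from N(12, 1) and absent
cells are missing. Real label-free data additionally have
intensity-dependent missingness, correlated peptides and batch effects;
the simulator plants the presence signal the screen is designed to
detect and nothing else.

## Problem sizes and defaults

Test and example runs use 2–10 genes, 1 020–2 000 peptides, 80 samples,
10 simulation seeds, and exhaustive 5-of-26 panel searches (65 780
combinations) — sizes chosen so the full suite exercises every code
path, including the exhaustive search, while remaining comfortable on a
single CPU. All randomness flows from explicit integer seeds;
identical seeds give identical files, weights and selections.

## Known limitations

* Genes are processed independently; overlapping genes on opposite
  strands are not reconciled.
* No in-silico tryptic digestion, SNP/PTM variant peptides, or search
  engine invocation — the database is the search engine's *input*.
* The Storey smoother is a cubic polynomial trend, not a spline with a
  fixed degrees-of-freedom; on well-behaved p-value histograms the two
  agree to well within the π0 tolerances used here.
* Quantile normalization with heavy, structured missingness is
  approximate (common-grid interpolation).
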