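# isopept

Alternative-splicing isoforms leave peptide-level fingerprints: a peptide
spanning an exon–exon, exon–intron or intron–exon boundary is direct
evidence for one specific splice form. Standard MS/MS search databases
contain only annotated proteins, so these *isoform junction peptides*
(IJPs) are invisible to them. `isopept` is a toolkit for plasma
proteomics studies that

1. **builds an IJP search database** from gene structures: overlapping
   annotated exons are merged into serial-numbered *exon groups*, and
   every exon, exon–exon pair (adjacent = *normal*, non-adjacent =
   *exon skipping*), exon–intron and intron–exon boundary is translated
   in three reading frames, validated against stop codons, labeled
   knowledge-based (`_KB`, substring of a known transcript protein of the
   same gene) or theoretical (`_TH`), and written as search-ready FASTA;
2. **screens case/control presence–absence data for isoform markers**:
   intensities are log2-transformed and quantile-normalized, peptides are
   called present per sample against a quality threshold, and each
   peptide's 2×2 presence table (health vs cancer) is tested by Pearson
   chi-square with Benjamini–Hochberg adjusted p-values and
   Storey–Tibshirani q-values; markers are declared at *q* < 0.05, with
   expected false positives `q-threshold × #declared`;
3. **validates markers** with the per-gene Explainable Index
   `α = ((#con_C+1)/(#inc_C+1)) · ((#con_H+1)/(#inc_H+1))`, which rewards
   marker sets telling a coherent splicing story (e.g. exon E_j present
   in health while skipping junction E_iE_k, i<j<k, is present in
   cancer), and
4. **selects classifier panels**: every N-marker combination trains an
   N-7-2 sigmoid feed-forward network (outcome coding cancer = (1,0),
   healthy = (0,1)) on the training cohort and is ranked by the ROC AUC
   of its cancer score on an independent test cohort. Training is
   vectorized across combinations, so exhaustive C(26,5) = 65 780-panel
   searches finish in under a minute.

A synthetic-data module generates toy genomes with known exon-group
structure and simulated 40-vs-40 case/control studies with planted
differential peptides, so the whole pipeline is testable offline.

Coordinates are 1-based inclusive (GTF convention); minus-strand genes
are handled in transcription orientation (group 1 is the 5'-most group,
sequences are reverse-complemented).

## Worked example

```sh
python examples/screen_markers.py
```

prints (seed 1):

```
peptides screened:    1020
pi0 estimate:         1.000
selected at q<0.05:   22
planted recovered:    20/20
false selections:     2
expected false pos.:  1.10  (= 0.05 x #declared)
```

All 20 planted markers (present with probability 0.9 in cancer vs 0.1 in
health) are recovered, with two false selections — in line with the
expected 0.05 × 22 = 1.1 false positives among the declared markers;
`pi0` is the estimated null fraction. The other examples
(`build_database.py`, `explainable_index.py`, `select_panel.py`) walk
through database construction, Explainable Index scoring and panel
selection the same way.

The `isopept` CLI wires the same stages for shell use:

```sh
isopept simulate --seed 1 --outdir fixtures/
isopept genemodel --gtf fixtures/genes.gtf --fasta fixtures/genome.fa \
    --proteins fixtures/proteins.fa --out models.json
isopept build-db --models models.json --out peptides.fasta --stats stats.tsv
isopept screen --matrix fixtures/intensities.tsv \
    --groups fixtures/groups.tsv --out markers.tsv
isopept explain --markers markers.tsv --out genes.tsv
isopept run --config pipeline.yaml     # the whole thing, reproducibly
```

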