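import numpy as np
import pytest
from Bio.Seq import Seq

from isopept.genemodel import (ExonGroup, GeneModel, GenomicInterval, Intron,
                               Transcript, read_gene_models)
from isopept.synthdata import SimulationConfig, make_toy_genome


def gene_from_segments(exon_seqs, intron_seqs, strand="+", gene_id="gX",
                       transcripts=None, gene_start=1):
    """Build a GeneModel directly from transcription-orientation segments.

    ``exon_seqs`` and ``intron_seqs`` interleave as e1 i1 e2 i2 ... eN;
    each exon becomes a single-member group.  The locus sequence is laid
    out on the requested strand so coordinate arithmetic is exercised.
    """
    assert len(intron_seqs) == max(0, len(exon_seqs) - 1)
    segs = []
    for i, e in enumerate(exon_seqs):
        segs.append(("exon", i + 1, e))
        if i < len(intron_seqs):
            segs.append(("intron", i + 1, intron_seqs[i]))
    gene_nt = "".join(s[2] for s in segs)
    locus = gene_nt if strand == "+" else str(Seq(gene_nt).reverse_complement())

    groups, introns = [], []
    offset = 0
    total = len(gene_nt)
    for kind, serial, seq in segs:
        if strand == "+":
            start = gene_start + offset
            end = start + len(seq) - 1
        else:
            end = gene_start + total - 1 - offset
            start = end - len(seq) + 1
        iv = GenomicInterval("chrT", start, end, strand)
        if kind == "exon":
            groups.append(ExonGroup(serial=serial, members=(iv,), span=iv))
        else:
            introns.append(Intron(serial=serial, interval=iv))
        offset += len(seq)
    model = GeneModel(gene_id=gene_id, chrom="chrT", strand=strand,
                      exon_groups=groups, introns=introns,
                      transcripts=[], locus_seq=locus, locus_start=gene_start)
    for tx_id, protein in (transcripts or {}).items():
        model.transcripts.append(Transcript(
            id=tx_id, gene_id=gene_id, exons=[g.span for g in groups],
            phases=[None] * len(groups), protein=protein))
    return model


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    cfg = SimulationConfig(seed=7, n_genes=4, groups_per_gene=(3, 4))
    return cfg, make_toy_genome(cfg, tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def toy_models(toy_genome):
    _, toy = toy_genome
    return read_gene_models(toy.gtf_path, toy.fasta_path,
                            toy.protein_fasta_path)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
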