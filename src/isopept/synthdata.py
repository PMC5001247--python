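"""Synthetic genomes and case/control studies with planted markers.

The generator produces the inputs every other stage consumes, with known
ground truth:

* a toy genome FASTA plus GTF whose genes have a known number of exon
  groups (optionally with overlapping member exons) and sense-codon
  segments, so frame-0 translations are stop-free and one annotated
  transcript per gene supplies knowledge-based (``_KB``) evidence while
  the other frames and skip/retention junctions exercise the theoretical
  (``_TH``) path;
* a simulated case/control intensity study in the 40-vs-40 plasma design:
  peptides are present per-sample with group-specific probabilities
  (planted markers differ between groups, nulls share a background rate),
  and present cells receive log-normal intensities while absent cells are
  missing.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


__all__ = ["SimulationConfig", "ToyGenome", "make_toy_genome", "simulate_study"]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Study and genome parameters; defaults mirror a 40-vs-40 design."""

    seed: int = 0
    # genome
    n_genes: int = 5
    groups_per_gene: tuple[int, int] = (2, 5)
    exon_codons: tuple[int, int] = (12, 60)     # 36-180 nt per exon group
    intron_codons: tuple[int, int] = (10, 40)   # 30-120 nt per intron
    overlapping_exons: bool = True
    intergenic_nt: int = 30
    # study
    n_health: int = 40
    n_cancer: int = 40
    n_null_peptides: int = 1000
    n_planted: int = 20
    p_present_cancer: float = 0.9
    p_present_health: float = 0.1
    background_presence: float = 0.5
    log2_intensity_mean: float = 12.0
    log2_intensity_sd: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_present_cancer, self.p_present_health,
                  self.background_presence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability out of [0,1]: {p}")
        if self.exon_codons[0] < 1 or self.intron_codons[0] < 1:
            raise ValueError("segments need at least one codon (3 nt)")
        if self.groups_per_gene[0] < 1:
            raise ValueError("genes need at least one exon group")


@dataclass
class ToyGenome:
    """Generated files plus the ground-truth structure per gene."""

    fasta_path: Path
    gtf_path: Path
    protein_fasta_path: Path
    structure: dict[str, dict]  # gene_id -> {n_groups, n_introns, strand}


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _random_codons(rng, n: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n))


def make_toy_genome(cfg: SimulationConfig, outdir) -> ToyGenome:
    """Write genome FASTA, exon GTF and transcript-protein FASTA.

    Each gene alternates strand and carries one annotated transcript
    (``<gene>_t1``) whose exons are the full group spans with phase 0,
    plus, when ``cfg.overlapping_exons``, a second transcript whose exons
    are trimmed sub-intervals — giving groups more than one member
    without changing the grouping.  Files are byte-identical for equal
    configurations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    chrom = "chr1"
    chrom_parts: list[str] = []
    pos = 1  # next free 1-based coordinate
    gtf_lines: list[str] = []
    proteins: list[tuple[str, str]] = []
    structure: dict[str, dict] = {}

    from isopept.ijpdb import translate

    for g in range(cfg.n_genes):
        gene_id = f"g{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        n_groups = int(rng.integers(cfg.groups_per_gene[0],
                                    cfg.groups_per_gene[1] + 1))
        exon_seqs = [_random_codons(rng, int(rng.integers(*cfg.exon_codons)))
                     for _ in range(n_groups)]
        intron_seqs = [_random_codons(rng, int(rng.integers(*cfg.intron_codons)))
                       for _ in range(max(0, n_groups - 1))]

        # transcription-orientation gene sequence: e1 i1 e2 i2 ... eN
        segs = []
        for i, e in enumerate(exon_seqs):
            segs.append(("exon", i + 1, e))
            if i < len(intron_seqs):
                segs.append(("intron", i + 1, intron_seqs[i]))
        gene_nt = "".join(s[2] for s in segs)

        spacer = "".join(rng.choice(list("ACGT"))
                         for _ in range(cfg.intergenic_nt))
        chrom_parts.append(spacer)
        pos += len(spacer)
        gene_start = pos
        chrom_parts.append(gene_nt if strand == "+" else _revcomp(gene_nt))
        pos += len(gene_nt)

        # genomic coordinates of each transcription-order segment
        coords = []
        offset = 0
        for kind, serial, seq in segs:
            if strand == "+":
                start = gene_start + offset
                end = start + len(seq) - 1
            else:
                end = gene_start + len(gene_nt) - 1 - offset
                start = end - len(seq) + 1
            coords.append((kind, serial, start, end, len(seq)))
            offset += len(seq)

        exon_coords = [(s, st, en) for kind, s, st, en, _ in coords
                       if kind == "exon"]

        def gtf_line(tx_id, start, end, frame):
            return (f"{chrom}\ttoy\texon\t{start}\t{end}\t.\t{strand}\t{frame}"
                    f"\tgene_id \"{gene_id}\"; transcript_id \"{tx_id}\";")

        for serial, start, end in exon_coords:
            gtf_lines.append(gtf_line(f"{gene_id}_t1", start, end, "0"))
        t1_protein = translate("".join(exon_seqs), 0)
        proteins.append((f"{gene_id}_t1", t1_protein))

        if cfg.overlapping_exons:
            t2 = []
            for serial, start, end in exon_coords:
                if end - start + 1 >= 18:
                    t2.append((start + 3, end - 3))
                else:
                    t2.append((start, end))
            for start, end in t2:
                gtf_lines.append(gtf_line(f"{gene_id}_t2", start, end, "."))
            t2_nt = []
            for (serial, start, end), (s2, e2) in zip(exon_coords, t2):
                seq = exon_seqs[serial - 1]
                if strand == "+":
                    t2_nt.append(seq[s2 - start:len(seq) - (end - e2)])
                else:
                    t2_nt.append(seq[end - e2:len(seq) - (s2 - start)])
            proteins.append((f"{gene_id}_t2", translate("".join(t2_nt), 0)))

        structure[gene_id] = {
            "n_groups": n_groups,
            "n_introns": max(0, n_groups - 1),
            "strand": strand,
        }

    chrom_parts.append("".join(rng.choice(list("ACGT"))
                               for _ in range(cfg.intergenic_nt)))
    chrom_seq = "".join(chrom_parts)

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(chrom_seq), 60):
            fh.write(chrom_seq[i:i + 60] + "\n")
    gtf_path = outdir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    protein_path = outdir / "proteins.fa"
    with open(protein_path, "w") as fh:
        for tx_id, protein in proteins:
            fh.write(f">{tx_id}\n")
            for i in range(0, len(protein), 60):
                fh.write(protein[i:i + 60] + "\n")
    return ToyGenome(fasta_path=fasta_path, gtf_path=gtf_path,
                     protein_fasta_path=protein_path, structure=structure)


def simulate_study(
    cfg: SimulationConfig,
    peptide_ids: list[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a case/control intensity study with planted markers.

    Returns ``(intensities, groups, truth)``: a peptides x samples matrix
    (NaN where absent), a sample -> {health, cancer} label series, and a
    truth table flagging the planted differential peptides.  Peptide rows
    come from ``peptide_ids`` when given (the first ``n_planted`` of a
    seeded shuffle are planted), otherwise synthetic ids are created for
    ``n_planted`` planted plus ``n_null_peptides`` null rows.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if peptide_ids is None:
        ids = ([f"planted{i:03d}" for i in range(cfg.n_planted)]
               + [f"null{i:04d}" for i in range(cfg.n_null_peptides)])
        planted = set(ids[:cfg.n_planted])
    else:
        if cfg.n_planted > len(peptide_ids):
            raise ValueError("more planted markers requested than peptides")
        ids = list(peptide_ids)
        shuffled = list(ids)
        rng.shuffle(shuffled)
        planted = set(shuffled[:cfg.n_planted])

    samples = ([f"H{i + 1:02d}" for i in range(cfg.n_health)]
               + [f"C{i + 1:02d}" for i in range(cfg.n_cancer)])
    groups = pd.Series(["health"] * cfg.n_health + ["cancer"] * cfg.n_cancer,
                       index=samples)

    n_pep, n_samp = len(ids), len(samples)
    p = np.full((n_pep, n_samp), cfg.background_presence)
    is_cancer = (groups == "cancer").to_numpy()
    for r, pep in enumerate(ids):
        if pep in planted:
            p[r, :] = np.where(is_cancer, cfg.p_present_cancer,
                               cfg.p_present_health)
    present = rng.random((n_pep, n_samp)) < p
    log2_int = rng.normal(cfg.log2_intensity_mean, cfg.log2_intensity_sd,
                          size=(n_pep, n_samp))
    intensities = np.where(present, np.exp2(log2_int), np.nan)

    truth = pd.DataFrame({
        "peptide": ids,
        "planted": [pep in planted for pep in ids],
        "p_present_cancer": [cfg.p_present_cancer if pep in planted
                             else cfg.background_presence for pep in ids],
        "p_present_health": [cfg.p_present_health if pep in planted
                             else cfg.background_presence for pep in ids],
    })
    return (pd.DataFrame(intensities, index=ids, columns=samples),
            groups, truth)
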