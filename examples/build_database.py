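"""Build an isoform junction peptide database from a toy genome.

Generates a small genome + GTF with known exon-group structure, ingests
it into gene models, enumerates and validates all junction peptides, and
prints the per-category database statistics.
"""

from tempfile import TemporaryDirectory

from isopept import SimulationConfig, build_database, make_toy_genome, read_gene_models

cfg = SimulationConfig(seed=1, n_genes=4, groups_per_gene=(3, 4))
with TemporaryDirectory() as tmp:
    toy = make_toy_genome(cfg, tmp)
    models = read_gene_models(toy.gtf_path, toy.fasta_path,
                              toy.protein_fasta_path)

peptides, stats = build_database(models)

print(f"genes: {len(models)}, candidate peptides kept: {stats.total}")
for name, value in stats.to_rows():
    print(f"  {name:<24}{value}")
print("""
The five categories are exon peptides (EXON_KB), exon-exon junctions that
match a known transcript protein (E_E_KB) or not (E_E_TH), and the two
intron-retention junction types (E_I_TH right, I_E_TH left).  Normal vs
skipping splits E_E by whether the joined exon groups are adjacent.""")
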