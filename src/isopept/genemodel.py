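"""Gene structure ingestion: exon grouping, intron derivation, transcripts.

Coordinates throughout are 1-based inclusive genomic positions (the GTF
dialect).  Exons that overlap by at least one base are merged into *exon
groups*; groups receive serial numbers in transcription order (group 1 is
the 5'-most group of the transcript, i.e. the most downstream genomic
interval for a minus-strand gene).  Introns are the gaps between adjacent
group spans.  All sequence access is in transcription orientation: minus
strand genes return the reverse complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval", "ExonGroup", "Intron", "Transcript", "GeneModel",
    "group_overlapping_exons", "derive_introns", "read_gene_models",
    "write_models_json", "read_models_json",
]

_VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be positive: {self}")
        if self.start > self.end:
            raise ValueError(f"start > end: {self}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be + or -: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base on the same chromosome."""
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass(frozen=True)
class ExonGroup:
    """A set of mutually overlapping exons, serial-numbered along the gene."""

    serial: int
    members: tuple[GenomicInterval, ...]
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValueError("group serials are 1-based")
        if not self.members:
            raise ValueError("an exon group needs at least one member")


@dataclass(frozen=True)
class Intron:
    """The gap between exon group ``serial`` and group ``serial + 1``."""

    serial: int
    interval: GenomicInterval


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list[GenomicInterval]
    phases: list[int | None] = field(default_factory=list)
    protein: str = ""


@dataclass
class GeneModel:
    """One gene: exon groups, introns, transcripts and locus sequence.

    ``locus_seq`` is the plus-strand genomic sequence covering
    ``locus_start .. locus_start + len(locus_seq) - 1``; :meth:`sequence`
    extracts any sub-interval in transcription orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    exon_groups: list[ExonGroup]
    introns: list[Intron]
    transcripts: list[Transcript]
    locus_seq: str = ""
    locus_start: int = 1

    def sequence(self, interval: GenomicInterval) -> str:
        """Nucleotides of ``interval`` in transcription orientation."""
        lo = interval.start - self.locus_start
        hi = interval.end - self.locus_start + 1
        if lo < 0 or hi > len(self.locus_seq):
            raise IndexError(
                f"{interval.chrom}:{interval.start}-{interval.end} outside "
                f"the stored locus of gene {self.gene_id}")
        nt = self.locus_seq[lo:hi]
        if self.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        return nt

    def group_by_serial(self, serial: int) -> ExonGroup:
        return self.exon_groups[serial - 1]

    def intron_by_serial(self, serial: int) -> Intron | None:
        for intron in self.introns:
            if intron.serial == serial:
                return intron
        return None

    @property
    def n_groups(self) -> int:
        return len(self.exon_groups)


def _transcription_sort_key(strand: str):
    if strand == "+":
        return lambda iv: (iv.start, iv.end)
    return lambda iv: (-iv.end, -iv.start)


def group_overlapping_exons(exons: Sequence[GenomicInterval]) -> list[ExonGroup]:
    """Merge overlapping exons into serial-numbered groups.

    Groups are the connected components of the pairwise-overlap graph
    (overlap means sharing >= 1 base; merely touching intervals stay
    separate).  Serials follow transcription order, so for minus-strand
    input group 1 is the interval set with the highest genomic coordinates.

    Raises ``ValueError`` on mixed chromosomes or strands.
    """
    if not exons:
        return []
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError(
            f"exons span multiple chromosomes/strands: {chroms}, {strands}")
    strand = strands.pop()

    # sweep in genome order; a new component starts when the next exon
    # begins strictly after the running span end
    by_pos = sorted(exons, key=lambda iv: (iv.start, iv.end))
    components: list[list[GenomicInterval]] = [[by_pos[0]]]
    span_end = by_pos[0].end
    for exon in by_pos[1:]:
        if exon.start <= span_end:
            components[-1].append(exon)
        else:
            components.append([exon])
        span_end = max(span_end, exon.end)

    if strand == "-":
        components.reverse()

    groups = []
    for serial, members in enumerate(components, start=1):
        span = GenomicInterval(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            strand=strand,
        )
        ordered = tuple(sorted(members, key=_transcription_sort_key(strand)))
        groups.append(ExonGroup(serial=serial, members=ordered, span=span))
    return groups


def derive_introns(groups: Sequence[ExonGroup]) -> list[Intron]:
    """Introns between consecutive exon-group spans.

    Intron ``i`` fills the gap between group ``i`` and group ``i + 1`` in
    transcription order; book-ended groups (zero-length gap) yield no
    intron for that position.
    """
    introns: list[Intron] = []
    for left, right in zip(groups, groups[1:]):
        strand = left.span.strand
        if strand == "+":
            gap_start, gap_end = left.span.end + 1, right.span.start - 1
        else:
            gap_start, gap_end = right.span.end + 1, left.span.start - 1
        if gap_start > gap_end:
            continue
        introns.append(Intron(
            serial=left.serial,
            interval=GenomicInterval(left.span.chrom, gap_start, gap_end, strand),
        ))
    return introns


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf_exons(gtf_path) -> list[dict]:
    records = []
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2].lower() != "exon":
                continue
            attrs = _parse_gtf_attributes(fields[8])
            frame = fields[7]
            records.append({
                "chrom": fields[0],
                "start": int(fields[3]),
                "end": int(fields[4]),
                "strand": fields[6],
                "phase": int(frame) if frame in ("0", "1", "2") else None,
                "gene_id": attrs.get("gene_id", ""),
                "transcript_id": attrs.get("transcript_id", ""),
            })
    return records


def translate_frames(nt: str) -> str:
    """Longest stop-free translation among the three forward frames.

    Ties go to the lowest frame.  Used for transcript proteins when no
    annotated phase is available.
    """
    from isopept.ijpdb import translate  # local import avoids a cycle

    best = ""
    for frame in range(3):
        aa = translate(nt, frame)
        aa = aa.split("*", 1)[0]
        if len(aa) > len(best):
            best = aa
    return best


def _transcript_protein(tx: Transcript, gene: GeneModel) -> str:
    from isopept.ijpdb import translate

    order = _transcription_sort_key(gene.strand)
    exons = sorted(tx.exons, key=order)
    nt = "".join(gene.sequence(e) for e in exons)
    phases = [p for p in tx.phases if p is not None]
    if phases and tx.phases and tx.phases[0] is not None:
        # the GTF frame of the 5'-most exon gives the codon offset
        aa = translate(nt, tx.phases[0])
        return aa.split("*", 1)[0]
    return translate_frames(nt)


def read_gene_models(
    gtf_path,
    fasta_path,
    protein_fasta_path=None,
    locus_margin: int = 0,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per ``gene_id`` in a GTF.

    Exon records are grouped per gene across all of the gene's
    transcripts; transcript proteins come from ``protein_fasta_path``
    (records keyed by transcript id) when given, otherwise from
    translating the spliced exon chain (annotated phase if present, else
    the longest stop-free frame).
    """
    exon_records = _read_gtf_exons(gtf_path)
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    proteins = {}
    if protein_fasta_path is not None:
        proteins = {rec.id: str(rec.seq)
                    for rec in SeqIO.parse(str(protein_fasta_path), "fasta")}

    by_gene: dict[str, list[dict]] = {}
    for rec in exon_records:
        by_gene.setdefault(rec["gene_id"], []).append(rec)

    models = []
    for gene_id, recs in by_gene.items():
        chrom = recs[0]["chrom"]
        strand = recs[0]["strand"]
        if chrom not in genome:
            raise IOError(f"chromosome {chrom!r} missing from FASTA")
        chrom_seq = genome[chrom]
        intervals = []
        for r in recs:
            if r["end"] > len(chrom_seq):
                raise ValueError(
                    f"exon {r['chrom']}:{r['start']}-{r['end']} exceeds "
                    f"sequence length {len(chrom_seq)}")
            intervals.append(GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]))

        groups = group_overlapping_exons(intervals)
        introns = derive_introns(groups)

        lo = max(1, min(iv.start for iv in intervals) - locus_margin)
        hi = min(len(chrom_seq), max(iv.end for iv in intervals) + locus_margin)
        model = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand,
            exon_groups=groups, introns=introns, transcripts=[],
            locus_seq=chrom_seq[lo - 1:hi], locus_start=lo,
        )

        by_tx: dict[str, list[dict]] = {}
        for r in recs:
            by_tx.setdefault(r["transcript_id"], []).append(r)
        for tx_id, tx_recs in by_tx.items():
            order = _transcription_sort_key(strand)
            ivs = [GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"])
                   for r in tx_recs]
            pairs = sorted(zip(ivs, [r["phase"] for r in tx_recs]),
                           key=lambda p: order(p[0]))
            tx = Transcript(
                id=tx_id, gene_id=gene_id,
                exons=[p[0] for p in pairs],
                phases=[p[1] for p in pairs],
            )
            tx.protein = proteins.get(tx_id) or _transcript_protein(tx, model)
            model.transcripts.append(tx)
        models.append(model)
    return models


# -- JSON round-trip (artifact plumbing for the CLI) -------------------------

def _iv_to_list(iv: GenomicInterval) -> list:
    return [iv.chrom, iv.start, iv.end, iv.strand]


def write_models_json(models: Iterable[GeneModel], path) -> None:
    payload = []
    for g in models:
        payload.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "locus_start": g.locus_start, "locus_seq": g.locus_seq,
            "groups": [{"serial": grp.serial,
                        "members": [_iv_to_list(m) for m in grp.members]}
                       for grp in g.exon_groups],
            "introns": [{"serial": i.serial, "interval": _iv_to_list(i.interval)}
                        for i in g.introns],
            "transcripts": [{"id": t.id, "exons": [_iv_to_list(e) for e in t.exons],
                             "phases": t.phases, "protein": t.protein}
                            for t in g.transcripts],
        })
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_models_json(path) -> list[GeneModel]:
    with open(path) as fh:
        payload = json.load(fh)
    models = []
    for g in payload:
        groups = []
        for grp in g["groups"]:
            members = tuple(GenomicInterval(*m) for m in grp["members"])
            span = GenomicInterval(
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
                members[0].strand)
            groups.append(ExonGroup(grp["serial"], members, span))
        introns = [Intron(i["serial"], GenomicInterval(*i["interval"]))
                   for i in g["introns"]]
        transcripts = [Transcript(t["id"], g["gene_id"],
                                  [GenomicInterval(*e) for e in t["exons"]],
                                  t["phases"], t["protein"])
                       for t in g["transcripts"]]
        models.append(GeneModel(
            gene_id=g["gene_id"], chrom=g["chrom"], strand=g["strand"],
            exon_groups=groups, introns=introns, transcripts=transcripts,
            locus_seq=g["locus_seq"], locus_start=g["locus_start"]))
    return models
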