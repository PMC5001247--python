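"""Isoform junction peptide (IJP) database construction.

From each gene's exon groups and introns, four junction joining types are
enumerated alongside plain exon peptides:

* exon-exon between adjacent groups (*normal*) — evidence for the
  annotated splice form;
* exon-exon between non-adjacent groups (*skipping*) — evidence for
  exon-skipping isoforms;
* exon-intron and intron-exon — right and left intron-retention
  junctions.

Junction windows are translated in all three reading frames and validated:
a stop codon upstream of the junction (or anywhere, for the types listed
in :func:`validate_orf`) discards the frame.  Peptides found as substrings
of a known transcript protein of the same gene are labeled knowledge-based
(``_KB``); everything else is theoretical (``_TH``).  The emitted FASTA is
suitable as a search database for MS/MS identification engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from isopept.genemodel import GeneModel

__all__ = [
    "JunctionType", "CandidatePeptide", "DatabaseStats",
    "enumerate_candidates", "translate", "build_junction_sequence",
    "validate_orf", "label_kb_or_th", "build_database",
    "write_fasta", "read_fasta",
    "MAX_JUNCTION_AA", "WINDOW_NT",
]

#: Junction peptides are capped at 140 residues — longer than the longest
#: peptide fragment observable in a single MS/MS spectrum.
MAX_JUNCTION_AA = 140

#: Nucleotides taken from each side of a junction: 210 per side lets every
#: one of the three frames reach the 140-aa cap.
WINDOW_NT = 3 * MAX_JUNCTION_AA // 2

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})


class JunctionType(Enum):
    EXON = "EXON"
    E_E_NORMAL = "E_E_NORMAL"
    E_E_SKIP = "E_E_SKIP"
    E_I = "E_I"
    I_E = "I_E"

    @property
    def is_exon_exon(self) -> bool:
        return self in (JunctionType.E_E_NORMAL, JunctionType.E_E_SKIP)

    @property
    def is_junction(self) -> bool:
        return self is not JunctionType.EXON


@dataclass(frozen=True)
class CandidatePeptide:
    """One translated candidate, keyed by (gene, type, serials, frame).

    ``junction_offset`` is the 0-based index of the first residue whose
    codon includes a base from the right-hand segment; junction peptides
    must have it in ``[1, len(sequence) - 1]`` so the peptide truly spans
    the boundary.  ``left_serial``/``right_serial`` are exon-group serials
    except that E_I uses (group i, intron i) and I_E (intron i, group i+1),
    both recorded under the intron's serial i.
    """

    gene_id: str
    jtype: JunctionType
    left_serial: int
    right_serial: int | None
    frame: int
    sequence: str
    junction_offset: int | None
    kb: bool

    @property
    def category(self) -> str:
        if self.jtype is JunctionType.EXON:
            return "EXON_KB"
        if self.jtype.is_exon_exon:
            return "E_E_KB" if self.kb else "E_E_TH"
        if self.jtype is JunctionType.E_I:
            return "E_I_TH"
        return "I_E_TH"

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.jtype.value, self.left_serial,
                self.right_serial, self.frame)


@dataclass
class DatabaseStats:
    """Category counts and length summaries of a built peptide database."""

    counts: dict[str, int]
    n_normal_ee: int
    n_skip_ee: int
    longest_exon: int
    average_exon: float
    longest_junction: int
    average_junction: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> list[tuple[str, object]]:
        rows: list[tuple[str, object]] = [
            (cat, self.counts.get(cat, 0))
            for cat in ("EXON_KB", "E_E_KB", "E_E_TH", "E_I_TH", "I_E_TH")]
        rows += [
            ("Total", self.total),
            ("Normal E_E", self.n_normal_ee),
            ("Skipping E_E", self.n_skip_ee),
            ("Longest Exon (aa)", self.longest_exon),
            ("Average Exon (aa)", round(self.average_exon, 1)),
            ("Longest Junction (aa)", self.longest_junction),
            ("Average Junction (aa)", round(self.average_junction, 1)),
        ]
        return rows


def translate(nt: str, frame: int) -> str:
    """Standard-genetic-code translation starting at offset ``frame``.

    Trailing partial codons are dropped; stops render as ``'*'``; codons
    containing non-ACGT characters render as ``'X'``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    nt = nt.upper()
    aa = []
    for i in range(frame, len(nt) - 2, 3):
        aa.append(_CODON_TABLE.get(nt[i:i + 3], "X"))
    return "".join(aa)


def enumerate_candidates(
    gene: GeneModel,
) -> list[tuple[JunctionType, int, int | None]]:
    """All candidate (type, left serial, right serial) triples for a gene.

    For G exon groups this yields G exon candidates, C(G,2) exon-exon
    pairs (G-1 normal, the rest skipping), and one exon-intron plus one
    intron-exon candidate per existing intron.
    """
    if gene.n_groups < 1:
        raise ValueError(f"gene {gene.gene_id} has no exon groups")
    out: list[tuple[JunctionType, int, int | None]] = []
    G = gene.n_groups
    for i in range(1, G + 1):
        out.append((JunctionType.EXON, i, None))
    for i in range(1, G + 1):
        for k in range(i + 1, G + 1):
            jt = JunctionType.E_E_NORMAL if k == i + 1 else JunctionType.E_E_SKIP
            out.append((jt, i, k))
    for intron in gene.introns:
        out.append((JunctionType.E_I, intron.serial, intron.serial))
        out.append((JunctionType.I_E, intron.serial, intron.serial + 1))
    return out


def build_junction_sequence(
    gene: GeneModel,
    jtype: JunctionType,
    left_serial: int,
    right_serial: int | None,
    window_nt: int = WINDOW_NT,
) -> tuple[str, int]:
    """Nucleotide window around a junction, in transcription orientation.

    Returns ``(sequence, boundary)`` where ``boundary`` is the number of
    left-segment nucleotides retained (up to ``window_nt`` from the end of
    the left segment, then up to ``window_nt`` from the start of the right
    segment).  Exon candidates return the full group span with boundary 0.
    """
    if jtype is JunctionType.EXON:
        return gene.sequence(gene.group_by_serial(left_serial).span), 0

    if jtype.is_exon_exon:
        left_nt = gene.sequence(gene.group_by_serial(left_serial).span)
        right_nt = gene.sequence(gene.group_by_serial(right_serial).span)
    elif jtype is JunctionType.E_I:
        intron = gene.intron_by_serial(left_serial)
        if intron is None:
            raise ValueError(f"gene {gene.gene_id} has no intron {left_serial}")
        left_nt = gene.sequence(gene.group_by_serial(left_serial).span)
        right_nt = gene.sequence(intron.interval)
    elif jtype is JunctionType.I_E:
        intron = gene.intron_by_serial(left_serial)
        if intron is None:
            raise ValueError(f"gene {gene.gene_id} has no intron {left_serial}")
        left_nt = gene.sequence(intron.interval)
        right_nt = gene.sequence(gene.group_by_serial(right_serial).span)
    else:  # pragma: no cover
        raise ValueError(jtype)

    left_part = left_nt[-window_nt:]
    right_part = right_nt[:window_nt]
    return left_part + right_part, len(left_part)


def junction_residue_offset(boundary: int, frame: int) -> int:
    """Index of the first residue whose codon reaches the right segment."""
    return max(0, math.ceil((boundary - frame - 2) / 3))


def validate_orf(candidate: CandidatePeptide) -> CandidatePeptide | None:
    """Apply the stop-codon discard rules; return the kept peptide or None.

    Exon, knowledge-based exon-exon, and intron-exon candidates are
    discarded on any stop.  Theoretical exon-exon and exon-intron
    candidates are discarded only when a stop falls in the first (left)
    segment; a stop at or past the junction truncates the peptide, and the
    truncated peptide must still span the junction to be kept.
    """
    seq = candidate.sequence
    if "*" not in seq:
        return candidate
    jt = candidate.jtype
    strict = (jt is JunctionType.EXON
              or jt is JunctionType.I_E
              or (jt.is_exon_exon and candidate.kb))
    if strict:
        return None
    stop = seq.index("*")
    off = candidate.junction_offset
    if off is None or stop < off:
        return None
    truncated = seq[:stop]
    if off >= len(truncated):
        return None
    return replace(candidate, sequence=truncated)


def label_kb_or_th(sequence: str, gene: GeneModel) -> bool:
    """True (knowledge-based) iff the peptide is a substring of any
    transcript protein of the *same* gene."""
    if "*" in sequence or not sequence:
        return False
    return any(sequence in tx.protein for tx in gene.transcripts if tx.protein)


def _exon_phase_frames(gene: GeneModel, serial: int) -> list[int]:
    """Annotated phases applicable to an exon group's span start."""
    span = gene.group_by_serial(serial).span
    tx_start = span.end if gene.strand == "-" else span.start
    frames = []
    for tx in gene.transcripts:
        for exon, phase in zip(tx.exons, tx.phases):
            if phase is None:
                continue
            exon_tx_start = exon.end if gene.strand == "-" else exon.start
            if exon_tx_start == tx_start and phase not in frames:
                frames.append(phase)
    return frames


def _exon_candidates(gene: GeneModel, serial: int) -> list[CandidatePeptide]:
    nt = gene.sequence(gene.group_by_serial(serial).span)
    phases = _exon_phase_frames(gene, serial)
    if phases:
        frames = sorted(phases)
    else:
        # no annotation: keep the single longest stop-free frame
        best_frame, best_aa = None, ""
        for frame in range(3):
            aa = translate(nt, frame)
            if "*" not in aa and len(aa) > len(best_aa):
                best_frame, best_aa = frame, aa
        frames = [] if best_frame is None else [best_frame]
    out = []
    for frame in frames:
        aa = translate(nt, frame)
        cand = CandidatePeptide(
            gene_id=gene.gene_id, jtype=JunctionType.EXON,
            left_serial=serial, right_serial=None, frame=frame,
            sequence=aa, junction_offset=None,
            kb=label_kb_or_th(aa, gene))
        kept = validate_orf(cand)
        if kept is not None and kept.sequence:
            out.append(kept)
    return out


def build_database(
    genes: Iterable[GeneModel],
    window_nt: int = WINDOW_NT,
) -> tuple[list[CandidatePeptide], DatabaseStats]:
    """Enumerate, translate, validate and label every candidate peptide.

    Junction candidates are translated in all three frames; exon
    candidates use the annotated phase when present, otherwise the longest
    stop-free frame.  Candidates are de-duplicated by
    (gene, type, serials, frame).
    """
    kept: dict[tuple, CandidatePeptide] = {}
    for gene in genes:
        for jtype, left, right in enumerate_candidates(gene):
            if jtype is JunctionType.EXON:
                for cand in _exon_candidates(gene, left):
                    kept.setdefault(cand.key, cand)
                continue
            window, boundary = build_junction_sequence(
                gene, jtype, left, right, window_nt)
            for frame in range(3):
                aa = translate(window, frame)
                if not aa:
                    continue
                aa = aa[:MAX_JUNCTION_AA]
                off = junction_residue_offset(boundary, frame)
                if off < 1 or off >= len(aa):
                    continue
                kb = (jtype.is_exon_exon and label_kb_or_th(aa, gene))
                cand = CandidatePeptide(
                    gene_id=gene.gene_id, jtype=jtype,
                    left_serial=left, right_serial=right, frame=frame,
                    sequence=aa, junction_offset=off, kb=kb)
                valid = validate_orf(cand)
                if valid is not None and valid.sequence:
                    kept.setdefault(valid.key, valid)
    peptides = list(kept.values())
    return peptides, compute_stats(peptides)


def compute_stats(peptides: Sequence[CandidatePeptide]) -> DatabaseStats:
    counts = {c: 0 for c in ("EXON_KB", "E_E_KB", "E_E_TH", "E_I_TH", "I_E_TH")}
    exon_lens, junc_lens = [], []
    n_normal = n_skip = 0
    for p in peptides:
        counts[p.category] += 1
        if p.jtype is JunctionType.EXON:
            exon_lens.append(len(p.sequence))
        else:
            junc_lens.append(len(p.sequence))
        if p.jtype is JunctionType.E_E_NORMAL:
            n_normal += 1
        elif p.jtype is JunctionType.E_E_SKIP:
            n_skip += 1
    return DatabaseStats(
        counts=counts, n_normal_ee=n_normal, n_skip_ee=n_skip,
        longest_exon=max(exon_lens, default=0),
        average_exon=float(sum(exon_lens)) / len(exon_lens) if exon_lens else 0.0,
        longest_junction=max(junc_lens, default=0),
        average_junction=float(sum(junc_lens)) / len(junc_lens) if junc_lens else 0.0,
    )


def _header(p: CandidatePeptide) -> str:
    right = "" if p.right_serial is None else str(p.right_serial)
    head = f"{p.gene_id}|{p.category}|{p.left_serial}-{right}|F{p.frame}"
    if p.junction_offset is not None:
        head += f" J{p.junction_offset}"
    return head


def write_fasta(peptides: Iterable[CandidatePeptide], path) -> None:
    """Write the search database as FASTA, 60-column wrapped sequences."""
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{_header(p)}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def read_fasta(path) -> list[CandidatePeptide]:
    """Read back a database written by :func:`write_fasta`."""
    from Bio import SeqIO

    _BY_CATEGORY = {
        "EXON_KB": JunctionType.EXON,
        "E_I_TH": JunctionType.E_I,
        "I_E_TH": JunctionType.I_E,
    }
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, category, serials, frame_tag = rec.id.split("|")
        left_s, _, right_s = serials.partition("-")
        left, right = int(left_s), (int(right_s) if right_s else None)
        parts = rec.description.split()
        offset = None
        if len(parts) > 1 and parts[1].startswith("J"):
            offset = int(parts[1][1:])
        if category in _BY_CATEGORY:
            jtype = _BY_CATEGORY[category]
        else:  # E_E: recover normal vs skipping from the serials
            jtype = (JunctionType.E_E_NORMAL if right == left + 1
                     else JunctionType.E_E_SKIP)
        out.append(CandidatePeptide(
            gene_id=gene_id, jtype=jtype, left_serial=left,
            right_serial=right, frame=int(frame_tag[1:]),
            sequence=str(rec.seq), junction_offset=offset,
            kb=category.endswith("_KB") and category != "EXON_KB"))
    return out
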