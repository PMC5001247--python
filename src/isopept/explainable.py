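"""Explainable Index: biological coherence of a gene's marker sets.

A gene's significant peptides split into a health marker set *H* and a
cancer marker set *C*; members are single-exon markers ``E_j`` (exon
group j) or junction markers ``E_i E_k`` (groups i < k).  A marker is
*consistent* when the two sets tell a coherent exon-skipping story —
e.g. an exon present in health whose skipping junction is present in
cancer — and *inconsistent* under the mirrored configuration.  The index

    alpha = ((#con_C + 1) / (#inc_C + 1)) * ((#con_H + 1) / (#inc_H + 1))

is > 1 for "more explainable" genes and <= 1 for "less-explainable" ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Iterable, Literal, Sequence, Union

__all__ = [
    "SingleExonMarker", "JunctionMarker", "GeneMarkerSets",
    "ConsistencyCounts", "classify_marker", "consistency_counts",
    "explainable_index", "summarize_genes",
]


@dataclass(frozen=True)
class SingleExonMarker:
    """Presence evidence for exon group ``j`` itself."""
    j: int


@dataclass(frozen=True)
class JunctionMarker:
    """Presence evidence for the junction joining groups ``i`` < ``k``."""
    i: int
    k: int

    def __post_init__(self) -> None:
        if not self.i < self.k:
            raise ValueError(f"junction marker needs i < k, got {self.i}, {self.k}")

    def spans(self, j: int) -> bool:
        return self.i < j < self.k


Marker = Union[SingleExonMarker, JunctionMarker]


@dataclass
class GeneMarkerSets:
    gene_id: str
    H: frozenset = frozenset()
    C: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.H = frozenset(self.H)
        self.C = frozenset(self.C)


@dataclass
class ConsistencyCounts:
    con_C: int = 0
    inc_C: int = 0
    con_H: int = 0
    inc_H: int = 0


def _junctions(markers: Iterable[Marker]):
    return [m for m in markers if isinstance(m, JunctionMarker)]


def _exons(markers: Iterable[Marker]):
    return [m for m in markers if isinstance(m, SingleExonMarker)]


def _satisfies(marker: Marker, exon_side: frozenset, junc_side: frozenset,
               everything: frozenset, scope: str) -> bool:
    """The three conditions, with ``exon_side`` the set that must hold the
    single-exon marker (H for consistency) and ``junc_side`` the set that
    must hold the junction marker (C for consistency).

    1. marker takes part in an (E_j in exon_side, E_i E_k in junc_side,
       i < j < k) pair;
    2. marker is an E_j in exon_side with no spanning junction;
    3. marker is an E_i E_k in junc_side with no interior E_j.

    ``scope`` decides whether the negations of conditions 2/3 quantify
    over both marker sets or only the set named by condition 1.
    """
    if isinstance(marker, SingleExonMarker):
        if marker not in exon_side:
            return False
        if any(jm.spans(marker.j) for jm in _junctions(junc_side)):
            return True  # condition 1 (as the exon participant)
        neg = everything if scope == "both" else junc_side
        return not any(jm.spans(marker.j) for jm in _junctions(neg))
    if marker not in junc_side:
        return False
    if any(marker.spans(em.j) for em in _exons(exon_side)):
        return True  # condition 1 (as the junction participant)
    neg = everything if scope == "both" else exon_side
    return not any(marker.spans(em.j) for em in _exons(neg))


def classify_marker(
    marker: Marker,
    sets: GeneMarkerSets,
    scope: Literal["both", "opposite"] = "both",
    policy: Literal["both_sides", "consistent_wins"] = "both_sides",
) -> str:
    """Classify one marker as consistent, inconsistent, both or neutral.

    ``scope`` controls which sets the "no spanning junction / no interior
    exon" negations quantify over; ``policy`` resolves markers that
    satisfy both a consistent and an inconsistent condition.
    """
    if marker not in sets.H and marker not in sets.C:
        raise ValueError(f"{marker} is in neither marker set of {sets.gene_id}")
    everything = sets.H | sets.C
    con = _satisfies(marker, _exon_subset(sets.H), _junc_subset(sets.C),
                     everything, scope)
    inc = _satisfies(marker, _exon_subset(sets.C), _junc_subset(sets.H),
                     everything, scope)
    if con and inc and policy == "consistent_wins":
        inc = False
    if con and inc:
        return "both"
    if con:
        return "consistent"
    if inc:
        return "inconsistent"
    return "neutral"


def _exon_subset(markers: frozenset) -> frozenset:
    return frozenset(m for m in markers if isinstance(m, SingleExonMarker))


def _junc_subset(markers: frozenset) -> frozenset:
    return frozenset(m for m in markers if isinstance(m, JunctionMarker))


def consistency_counts(
    sets: GeneMarkerSets,
    scope: Literal["both", "opposite"] = "both",
    policy: Literal["both_sides", "consistent_wins"] = "both_sides",
) -> ConsistencyCounts:
    """Tally consistent/inconsistent markers into the set each belongs to.

    A two-marker condition credits both participants: the E_j counts
    toward its own set's counter and the junction toward its set's.
    Markers satisfying conditions on both sides count once per side
    (``policy="both_sides"``) or only as consistent
    (``policy="consistent_wins"``).
    """
    counts = ConsistencyCounts()
    for marker in sets.H | sets.C:
        label = classify_marker(marker, sets, scope=scope, policy=policy)
        side = "C" if marker in sets.C else "H"
        if label in ("consistent", "both"):
            setattr(counts, f"con_{side}", getattr(counts, f"con_{side}") + 1)
        if label in ("inconsistent", "both"):
            setattr(counts, f"inc_{side}", getattr(counts, f"inc_{side}") + 1)
    return counts


def explainable_index(
    sets: GeneMarkerSets | ConsistencyCounts,
    scope: Literal["both", "opposite"] = "both",
    policy: Literal["both_sides", "consistent_wins"] = "both_sides",
) -> tuple[float, str]:
    """Compute alpha and its label for a gene.

    Accepts either the gene's marker sets (counts are derived via
    :func:`classify_marker`) or precomputed :class:`ConsistencyCounts`.
    """
    if isinstance(sets, ConsistencyCounts):
        c = sets
    else:
        c = consistency_counts(sets, scope=scope, policy=policy)
    alpha = ((c.con_C + 1) / (c.inc_C + 1)) * ((c.con_H + 1) / (c.inc_H + 1))
    label = "more explainable" if alpha > 1 else "less-explainable"
    return alpha, label


def summarize_genes(
    gene_sets: Sequence[GeneMarkerSets],
    scope: Literal["both", "opposite"] = "both",
) -> dict:
    """Mean/median/max alpha and more/less-explainable counts."""
    if not gene_sets:
        raise ValueError("no genes to summarize")
    alphas, n_more = [], 0
    for sets in gene_sets:
        alpha, label = explainable_index(sets, scope=scope)
        alphas.append(alpha)
        n_more += label == "more explainable"
    return {
        "mean_alpha": mean(alphas),
        "median_alpha": median(alphas),
        "max_alpha": max(alphas),
        "n_more_explainable": n_more,
        "n_less_explainable": len(alphas) - n_more,
        "alphas": alphas,
    }
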