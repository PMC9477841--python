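"""Strand-aware classification of cis-natural antisense transcript pairs.

Two genes form a cis-NAT pair when they sit on the same chromosome, on
opposite strands, and their gene spans share at least one base (closed
intervals, so touching at a single coordinate counts). Each directed
pair (target gene, antisense partner) is labelled with one of four
geometries:

``EB`` (embedded)
    the antisense gene's whole transcription unit lies within the
    target's unit;
``FO`` (fully-overlapped)
    the antisense gene's unit covers the target's whole unit (the dual
    of EB);
``HH`` (head-to-head)
    partial overlap at the two genes' 5' ends only — divergent
    transcription;
``TT`` (tail-to-tail)
    partial overlap at the two genes' 3' ends only — convergent
    transcription.

Containment (EB/FO) uses non-strict inequalities; the partial-overlap
types use strict outer inequalities so containment is never
double-reported as HH or TT. Consequently two genes with identical
spans satisfy both containment conditions and are reported as both EB
and FO — the only case where a directed pair carries two labels.

Every unordered overlapping pair has two directed representations with
dual types: EB<->FO, HH<->HH, TT<->TT. The full extraction therefore
runs in both directions (each gene appears as target and as candidate);
:func:`dedup_unordered` collapses the redundancy when a count of
distinct loci is wanted.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree

from .records import MINUS, PLUS, GeneRecord, GeneTable


class OverlapType(str, enum.Enum):
    """The four cis-NAT geometries."""

    EB = "EB"
    FO = "FO"
    HH = "HH"
    TT = "TT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def dual(self) -> "OverlapType":
        """Type carried by the reversed directed pair."""
        return _DUAL[self]


_DUAL = {
    OverlapType.EB: OverlapType.FO,
    OverlapType.FO: OverlapType.EB,
    OverlapType.HH: OverlapType.HH,
    OverlapType.TT: OverlapType.TT,
}


def tss_of(gene: GeneRecord) -> int:
    """Transcription start site: the 5' coordinate of the gene span."""
    return gene.start if gene.strand == PLUS else gene.end


def tts_of(gene: GeneRecord) -> int:
    """Transcription termination site: the 3' coordinate of the gene span."""
    return gene.end if gene.strand == PLUS else gene.start


class Bound(NamedTuple):
    """A one-sided constraint on a candidate coordinate."""

    site: str  # "tss" or "tts"
    relation: str  # one of <=, >=, <, >
    coordinate: int

    def holds(self, value: int) -> bool:
        if self.relation == "<=":
            return value <= self.coordinate
        if self.relation == ">=":
            return value >= self.coordinate
        if self.relation == "<":
            return value < self.coordinate
        if self.relation == ">":
            return value > self.coordinate
        raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class ScreeningCondition:
    """Coordinate predicate an antisense candidate must satisfy.

    Expressed on the candidate's TSS and TTS (named AS-TSS / AS-TTS in
    screening logs). ``tss_bound`` / ``tts_bound`` are the primary
    bounds; the partial-overlap geometries need one further bound each,
    kept in ``extra_bounds``.
    """

    target_id: str
    type: OverlapType
    candidate_strand: str
    tss_bound: Bound | None = None
    tts_bound: Bound | None = None
    extra_bounds: tuple[Bound, ...] = field(default_factory=tuple)

    def bounds(self) -> tuple[Bound, ...]:
        primary = tuple(b for b in (self.tss_bound, self.tts_bound) if b is not None)
        return primary + self.extra_bounds

    def satisfied_by(self, candidate: GeneRecord) -> bool:
        """True if the candidate's TSS/TTS meet every bound.

        Chromosome and strand screening are the caller's concern; this
        predicate is pure coordinate logic ("selection 2: location").
        """
        coords = {"tss": tss_of(candidate), "tts": tts_of(candidate)}
        return all(b.holds(coords[b.site]) for b in self.bounds())


def screening_condition(target: GeneRecord, type: OverlapType) -> ScreeningCondition:
    """Build the coordinate screen for one (target, type) combination.

    Let ``[S, E]`` be the target span and ``[a, b]`` a candidate span
    on the opposite strand. In genomic coordinates the four conditions
    are:

    * FO: ``a <= S and E <= b`` (candidate covers target)
    * EB: ``S <= a and b <= E`` (candidate inside target)
    * HH: both 5' ends, and neither 3' end, inside the shared region
      (``a < S <= b < E`` for a plus-strand target)
    * TT: both 3' ends, and neither 5' end, inside the shared region
      (``S < a <= E < b`` for a plus-strand target)

    For a minus-strand target the HH and TT interval forms swap. The
    returned condition restates these on the candidate's TSS/TTS, which
    is how the screen is logged: e.g. FO screening of a minus-strand
    target spanning 102,503,972-102,526,860 yields
    ``(AS-TSS <= 102,503,972) & (AS-TTS >= 102,526,860)``.
    """
    S, E = target.start, target.end
    cand_strand = MINUS if target.strand == PLUS else PLUS
    # candidate [a, b]: plus candidate has TSS=a, TTS=b; minus has TSS=b, TTS=a
    a_site = "tss" if cand_strand == PLUS else "tts"
    b_site = "tts" if cand_strand == PLUS else "tss"

    def cond(*bounds: Bound) -> ScreeningCondition:
        by_site: dict[str, Bound] = {}
        extras: list[Bound] = []
        for bd in bounds:
            if bd.site in by_site:
                extras.append(bd)
            else:
                by_site[bd.site] = bd
        return ScreeningCondition(
            target_id=target.gene_id,
            type=type,
            candidate_strand=cand_strand,
            tss_bound=by_site.get("tss"),
            tts_bound=by_site.get("tts"),
            extra_bounds=tuple(extras),
        )

    if type is OverlapType.FO:
        return cond(Bound(a_site, "<=", S), Bound(b_site, ">=", E))
    if type is OverlapType.EB:
        return cond(Bound(a_site, ">=", S), Bound(b_site, "<=", E))

    # partial overlaps: orientation depends on the target strand
    if (type is OverlapType.HH) == (target.strand == PLUS):
        # a < S <= b < E
        return cond(Bound(a_site, "<", S), Bound(b_site, ">=", S), Bound(b_site, "<", E))
    # S < a <= E < b
    return cond(Bound(a_site, ">", S), Bound(a_site, "<=", E), Bound(b_site, ">", E))


class CisNatPair(NamedTuple):
    """A directed cis-NAT pair: target gene, antisense partner, geometry."""

    target_id: str
    antisense_id: str
    type: OverlapType


class PairSet:
    """A set of directed pairs with per-pair pass provenance.

    Provenance names the extraction pass that produced a pair, e.g.
    ``"FO, minus-to-plus"`` — the target strand first, then the
    candidate strand.
    """

    def __init__(self, pairs: Iterable[CisNatPair] = (), provenance: dict[CisNatPair, str] | None = None):
        self._pairs: dict[CisNatPair, str] = {}
        provenance = provenance or {}
        for p in pairs:
            if p in self._pairs:
                raise ValueError(f"duplicate pair {p}")
            self._pairs[p] = provenance.get(p, "")

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __contains__(self, pair: CisNatPair) -> bool:
        return pair in self._pairs

    def provenance_of(self, pair: CisNatPair) -> str:
        return self._pairs[pair]

    def as_set(self) -> frozenset[CisNatPair]:
        return frozenset(self._pairs)

    def of_type(self, type: OverlapType) -> list[CisNatPair]:
        return [p for p in self._pairs if p.type is type]


def classify_candidate(target: GeneRecord, candidate: GeneRecord) -> set[OverlapType]:
    """Classify one candidate against one target.

    Returns the empty set when the two genes are on different
    chromosomes, on the same strand, are the same gene, or do not share
    a base; otherwise the set of geometries whose screening condition
    the candidate satisfies. By construction that set is a single type,
    except for identical spans which satisfy both EB and FO.
    """
    if target.chrom != candidate.chrom:
        return set()
    if target.strand == candidate.strand:
        return set()
    if candidate.end < target.start or candidate.start > target.end:
        return set()
    return {
        t for t in OverlapType if screening_condition(target, t).satisfied_by(candidate)
    }


def find_cisnats(table: GeneTable) -> PairSet:
    """Extract every directed cis-NAT pair from a gene table.

    Equivalent to classifying all ordered same-chromosome,
    opposite-strand gene pairs, run as four type passes in each strand
    direction (plus-to-minus, then minus-to-plus). An interval index
    per (chromosome, strand) restricts the location screen to genes
    that actually share a base, so the work is proportional to the
    number of overlaps rather than to all pairs.
    """
    # interval trees keyed by (chrom, strand); closed [start, end] -> [start, end+1)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in table:
        trees.setdefault((gene.chrom, gene.strand), IntervalTree()).addi(
            gene.start, gene.end + 1, gene
        )

    pairs: list[CisNatPair] = []
    provenance: dict[CisNatPair, str] = {}
    pass_order = [OverlapType.EB, OverlapType.FO, OverlapType.HH, OverlapType.TT]
    for target_strand, cand_strand, direction in (
        (PLUS, MINUS, "plus-to-minus"),
        (MINUS, PLUS, "minus-to-plus"),
    ):
        for type in pass_order:
            for (chrom, strand), tree in trees.items():
                if strand != target_strand:
                    continue
                cand_tree = trees.get((chrom, cand_strand))
                if cand_tree is None:
                    continue
                for iv in sorted(tree):
                    target: GeneRecord = iv.data
                    condition = screening_condition(target, type)
                    for civ in cand_tree.overlap(target.start, target.end + 1):
                        candidate: GeneRecord = civ.data
                        if condition.satisfied_by(candidate):
                            pair = CisNatPair(target.gene_id, candidate.gene_id, type)
                            pairs.append(pair)
                            provenance[pair] = f"{type.value}, {direction}"
    return PairSet(pairs, provenance)


def dedup_unordered(pairs: PairSet | Iterable[CisNatPair]) -> set[frozenset[str]]:
    """Collapse dual directed representations to unordered gene pairs.

    Every overlapping locus pair appears twice in a full extraction
    (EB with FO, HH with HH, TT with TT); the unordered view counts it
    once.
    """
    return {frozenset((p.target_id, p.antisense_id)) for p in pairs}


def summarize_types(pairs: PairSet, table: GeneTable) -> dict[str, dict[str, float]]:
    """Per-type counts of genes possessing a cis-NAT, with percentages.

    A gene is counted under type ``t`` when it is the *target* of at
    least one directed pair of that type; ``any`` is the union across
    types (identical whichever role is counted, by pair duality).
    Percentages are relative to all genes in the table.
    """
    total = len(table)
    by_type: dict[str, set[str]] = {t.value: set() for t in OverlapType}
    for p in pairs:
        by_type[p.type.value].add(p.target_id)
    any_genes = set(itertools.chain.from_iterable(by_type.values()))
    out: dict[str, dict[str, float]] = {}
    for label, genes in [("any", any_genes)] + [(t.value, by_type[t.value]) for t in OverlapType]:
        count = len(genes)
        out[label] = {
            "gene_count": count,
            "percentage": 100.0 * count / total if total else 0.0,
        }
    return out
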