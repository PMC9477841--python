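"""Independent brute-force reference classifier used only by tests.

Deliberately written from first principles — 5'/3' end membership in
the shared region, enumerated over all ordered gene pairs — and never
via the package's screening-condition machinery, so that agreement
between the two is a real cross-check.
"""

from __future__ import annotations

from cisnat.core import CisNatPair, OverlapType
from cisnat.records import GeneRecord, GeneTable


def oracle_classify(target: GeneRecord, cand: GeneRecord) -> set[OverlapType]:
    """Classify one ordered pair by end-point membership in the overlap."""
    if target.chrom != cand.chrom or target.strand == cand.strand:
        return set()
    lo = max(target.start, cand.start)
    hi = min(target.end, cand.end)
    if lo > hi:  # closed intervals: no shared base
        return set()
    types: set[OverlapType] = set()
    if target.start <= cand.start and cand.end <= target.end:
        types.add(OverlapType.EB)
    if cand.start <= target.start and target.end <= cand.end:
        types.add(OverlapType.FO)
    if not types:
        # partial overlap: which ends of BOTH genes fall inside [lo, hi]?
        def five(g: GeneRecord) -> int:
            return g.start if g.strand == "+" else g.end

        def three(g: GeneRecord) -> int:
            return g.end if g.strand == "+" else g.start

        both_five = lo <= five(target) <= hi and lo <= five(cand) <= hi
        both_three = lo <= three(target) <= hi and lo <= three(cand) <= hi
        if both_five and not both_three:
            types.add(OverlapType.HH)
        if both_three and not both_five:
            types.add(OverlapType.TT)
    return types


def oracle_find(table: GeneTable) -> set[CisNatPair]:
    """All-pairs extraction, grouped by chromosome for speed only."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in table:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: set[CisNatPair] = set()
    for genes in by_chrom.values():
        for t in genes:
            for c in genes:
                for typ in oracle_classify(t, c):
                    out.add(CisNatPair(t.gene_id, c.gene_id, typ))
    return out
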