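"""Synthetic gene tables with planted antisense-overlap geometry.

The generator lays genes out in disjoint per-chromosome slots so that
nothing overlaps anything outside its own slot. Each slot hosts one of:

* a planted cis-NAT pair of a requested geometry (embedded,
  fully-overlapped, head-to-head or tail-to-tail), built with margins
  of at least 2 bases at every boundary so that tie-breaking at shared
  coordinates is only ever exercised deliberately;
* an identical-span pair (two genes with the same interval on opposite
  strands — the one geometry that legitimately classifies as both EB
  and FO);
* a same-strand overlap decoy (two overlapping genes on one strand,
  which must never pair);
* a background gene overlapping nothing on the opposite strand.

The planted truth lists BOTH directed representations of every pair
(EB with its FO dual, HH and TT with their mirrored selves), which is
exactly what a full extraction must return. Planted expression
statuses are realized as (fold change, padj) values that the deg
caller maps back to the planted status under the same thresholds.

All randomness comes from one seeded ``numpy`` generator; no global
state is touched, and a given seed reproduces the fixture exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import CisNatPair, OverlapType
from .errors import InputError
from .expression import DOWN, NS, UP, DegThresholds
from .records import MINUS, PLUS, GeneRecord, GeneTable

import pandas as pd

_SLOT_WIDTH = 2_000
_SLOT_GAP = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults give a small multi-chromosome genome with a handful of
    each geometry — enough to exercise every code path while staying
    instantaneous to generate and classify.
    """

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    n_background_genes: int = 30
    planted: Mapping[OverlapType, int] = field(
        default_factory=lambda: {t: 3 for t in OverlapType}
    )
    n_same_strand_overlaps: int = 0
    n_identical_span_pairs: int = 0
    expression_profile: Mapping[tuple[str, str], int] = field(default_factory=dict)
    thresholds: DegThresholds = field(default_factory=DegThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise InputError("need at least one chromosome")
        counts = list(self.planted.values()) + [
            self.n_background_genes,
            self.n_same_strand_overlaps,
            self.n_identical_span_pairs,
        ] + list(self.expression_profile.values())
        if any(c < 0 for c in counts):
            raise InputError("all fixture counts must be >= 0")
        n_pairs = sum(self.planted.values())
        if sum(self.expression_profile.values()) > n_pairs:
            raise InputError(
                "expression_profile assigns more pairs than are planted"
            )


@dataclass
class FixtureTruth:
    """Ground truth for one fixture.

    ``pairs`` holds every expected directed triple; ``calls`` the
    planted status per gene (genes not listed are ``ns``);
    ``pair_statuses`` the (target status, antisense status) per
    directed pair.
    """

    pairs: list[CisNatPair]
    calls: dict[str, str]
    pair_statuses: dict[CisNatPair, tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target_id": p.target_id,
                "antisense_id": p.antisense_id,
                "Type": p.type.value,
                "target_status": self.pair_statuses.get(p, (NS, NS))[0],
                "antisense_status": self.pair_statuses.get(p, (NS, NS))[1],
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=["target_id", "antisense_id", "Type", "target_status", "antisense_status"],
        )


def _four_points(rng: np.random.Generator, lo: int) -> tuple[int, int, int, int]:
    """Four ascending coordinates in a slot, pairwise >= 3 apart."""
    gaps = rng.integers(10, 400, size=4)
    pts = lo + np.cumsum(gaps)
    return tuple(int(x) for x in pts)


def generate_fixture(spec: FixtureSpec) -> tuple[GeneTable, FixtureTruth]:
    """Build the gene table and its ground truth.

    Raises :class:`InputError` when the requested content cannot be
    placed within ``chrom_length``.
    """
    rng = np.random.default_rng(spec.seed)
    n_slots = (
        sum(spec.planted.values())
        + spec.n_identical_span_pairs
        + spec.n_same_strand_overlaps
        + spec.n_background_genes
    )
    slots_per_chrom = -(-n_slots // spec.n_chromosomes) if n_slots else 0
    if slots_per_chrom * (_SLOT_WIDTH + _SLOT_GAP) > spec.chrom_length:
        raise InputError(
            f"chrom_length {spec.chrom_length} too short for "
            f"{slots_per_chrom} slots per chromosome"
        )

    # slot contents, shuffled so geometries interleave across chromosomes
    contents: list[tuple[str, OverlapType | None]] = []
    for t in OverlapType:
        contents += [("pair", t)] * spec.planted.get(t, 0)
    contents += [("identical", None)] * spec.n_identical_span_pairs
    contents += [("decoy", None)] * spec.n_same_strand_overlaps
    contents += [("background", None)] * spec.n_background_genes
    rng.shuffle(contents)  # type: ignore[arg-type]

    records: list[GeneRecord] = []
    truth_pairs: list[CisNatPair] = []
    planted_directed: list[CisNatPair] = []  # canonical direction, planting order
    next_id = 0

    def new_id() -> str:
        nonlocal next_id
        next_id += 1
        return f"G{next_id:05d}"

    for slot_idx, (kind, ptype) in enumerate(contents):
        chrom = f"chr{slot_idx % spec.n_chromosomes + 1}"
        lo = 1 + (slot_idx // spec.n_chromosomes) * (_SLOT_WIDTH + _SLOT_GAP)

        if kind == "background":
            p1, p2, _, _ = _four_points(rng, lo)
            strand = PLUS if rng.random() < 0.5 else MINUS
            records.append(GeneRecord(new_id(), chrom, strand, p1, p2))
            continue

        if kind == "decoy":
            p1, p2, p3, p4 = _four_points(rng, lo)
            strand = PLUS if rng.random() < 0.5 else MINUS
            records.append(GeneRecord(new_id(), chrom, strand, p1, p3))
            records.append(GeneRecord(new_id(), chrom, strand, p2, p4))
            continue

        if kind == "identical":
            p1, p2, _, _ = _four_points(rng, lo)
            a_id, b_id = new_id(), new_id()
            records.append(GeneRecord(a_id, chrom, PLUS, p1, p2))
            records.append(GeneRecord(b_id, chrom, MINUS, p1, p2))
            for x, y in ((a_id, b_id), (b_id, a_id)):
                truth_pairs.append(CisNatPair(x, y, OverlapType.EB))
                truth_pairs.append(CisNatPair(x, y, OverlapType.FO))
            continue

        # planted pair of geometry ptype
        assert ptype is not None
        t_strand = PLUS if rng.random() < 0.5 else MINUS
        c_strand = MINUS if t_strand == PLUS else PLUS
        p1, p2, p3, p4 = _four_points(rng, lo)
        if ptype is OverlapType.EB:
            t_iv, c_iv = (p1, p4), (p2, p3)  # candidate strictly inside
        elif ptype is OverlapType.FO:
            t_iv, c_iv = (p2, p3), (p1, p4)  # candidate strictly covers
        elif (ptype is OverlapType.HH) == (t_strand == PLUS):
            t_iv, c_iv = (p2, p4), (p1, p3)  # a < S <= b < E form
        else:
            t_iv, c_iv = (p1, p3), (p2, p4)  # S < a <= E < b form
        t_id, c_id = new_id(), new_id()
        records.append(GeneRecord(t_id, chrom, t_strand, *t_iv))
        records.append(GeneRecord(c_id, chrom, c_strand, *c_iv))
        fwd = CisNatPair(t_id, c_id, ptype)
        truth_pairs.append(fwd)
        truth_pairs.append(CisNatPair(c_id, t_id, ptype.dual))
        planted_directed.append(fwd)

    # plant expression statuses on canonical directed pairs, in order
    calls: dict[str, str] = {}
    pair_statuses: dict[CisNatPair, tuple[str, str]] = {}
    assignments: list[tuple[str, str]] = []
    for combo, count in spec.expression_profile.items():
        for s in combo:
            if s not in (UP, DOWN, NS):
                raise InputError(f"unknown status {s!r} in expression_profile")
        assignments += [combo] * count
    for pair, (s_target, s_partner) in zip(planted_directed, assignments):
        calls[pair.target_id] = s_target
        calls[pair.antisense_id] = s_partner
        pair_statuses[pair] = (s_target, s_partner)
        dual = CisNatPair(pair.antisense_id, pair.target_id, pair.type.dual)
        pair_statuses[dual] = (s_partner, s_target)

    table = GeneTable(records)
    return table, FixtureTruth(truth_pairs, calls, pair_statuses)


def generate_expression(
    table: GeneTable, truth: FixtureTruth, spec: FixtureSpec
) -> GeneTable:
    """Attach ``fold-change``/``padj`` columns realizing planted statuses.

    Values are drawn so that the deg caller, run with ``spec.thresholds``,
    reproduces each gene's planted status exactly: up genes get fold
    change >= up_fc with padj < alpha, down genes fold change <= down_fc
    with padj < alpha, and ns genes either a non-significant padj or a
    fold change strictly inside (down_fc, up_fc).
    """
    rng = np.random.default_rng(spec.seed + 1)
    th = spec.thresholds
    records = []
    for gene in table:
        status = truth.calls.get(gene.gene_id, NS)
        if status == UP:
            fc = th.up_fc * (1.0 + 2.0 * rng.random())
            padj = th.alpha * rng.uniform(0.001, 0.9)
        elif status == DOWN:
            fc = th.down_fc * rng.uniform(0.2, 1.0)
            padj = th.alpha * rng.uniform(0.001, 0.9)
        elif rng.random() < 0.5:
            # non-significant p, arbitrary fold change
            fc = float(rng.uniform(0.2, 4.0))
            padj = float(rng.uniform(th.alpha, 1.0))
        else:
            # significant p but fold change inside the dead band
            fc = th.down_fc + (th.up_fc - th.down_fc) * rng.uniform(0.05, 0.95)
            padj = th.alpha * rng.uniform(0.001, 0.9)
        if th.fc_scale == "log2":
            fc = float(np.log2(fc))
        records.append(
            GeneRecord(
                gene.gene_id,
                gene.chrom,
                gene.strand,
                gene.start,
                gene.end,
                attrs={"fold-change": round(float(fc), 6), "padj": round(float(padj), 8)},
            )
        )
    return GeneTable(records, ["fold-change", "padj"])
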