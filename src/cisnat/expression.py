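"""Expression-profile crosstabs over cis-NAT pairs.

Each gene is called ``up``, ``down`` or ``ns`` (not significant) from
its fold change and adjusted p-value under explicit thresholds, and
directed pairs are cross-tabulated by geometry and by the (target,
antisense) status combination. Concordant (up-up / down-down) and
discordant (up-down / down-up) pair counts are reported over unordered
deduplicated pairs, since every locus pair appears in two dual directed
representations.

The status labels are contrast-agnostic: in an allele-bias contrast
"up" may read as maternally-biased and "down" as paternally-biased;
the engine only sees up/down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from .core import CisNatPair, OverlapType, PairSet, dedup_unordered
from .errors import InputError
from .records import GeneTable

UP = "up"
DOWN = "down"
NS = "ns"

#: deg statuses that enter the crosstab
_SIGNIFICANT = (UP, DOWN)


@dataclass(frozen=True)
class DegThresholds:
    """Differential-expression call thresholds.

    ``up_fc`` and ``down_fc`` are always stated on the linear fold-
    change scale (e.g. up >= 1.5, down <= 0.67); set
    ``fc_scale="log2"`` when the input column holds log2 fold changes,
    and values are converted with ``2**x`` before comparison.
    """

    alpha: float = 0.05
    up_fc: float = 1.5
    down_fc: float = 0.67
    fc_scale: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.down_fc < self.up_fc:
            raise InputError(
                f"down_fc ({self.down_fc}) must be below up_fc ({self.up_fc})"
            )
        if self.fc_scale not in ("linear", "log2"):
            raise InputError(f"fc_scale must be linear or log2, got {self.fc_scale!r}")


class ExpressionCall(NamedTuple):
    gene_id: str
    status: str  # up / down / ns


def call_deg(
    fold_change: float | None, padj: float | None, th: DegThresholds
) -> str:
    """Call one gene's status.

    ``up`` when padj < alpha and fold change >= up_fc; ``down`` when
    padj < alpha and fold change <= down_fc; otherwise ``ns``. A
    missing fold change or padj (None/NaN, as DESeq2 emits for
    low-count or outlier genes) is always ``ns``.
    """
    if fold_change is None or padj is None:
        return NS
    try:
        fc = float(fold_change)
        p = float(padj)
    except (TypeError, ValueError):
        return NS
    if math.isnan(fc) or math.isnan(p):
        return NS
    if th.fc_scale == "log2":
        fc = 2.0 ** fc
    if p >= th.alpha:
        return NS
    if fc >= th.up_fc:
        return UP
    if fc <= th.down_fc:
        return DOWN
    return NS


def call_table(
    table: GeneTable,
    th: DegThresholds,
    fc_col: str = "fold-change",
    padj_col: str = "padj",
) -> dict[str, str]:
    """Call every gene in a table from its pass-through columns."""
    for col in (fc_col, padj_col):
        if col not in table.attr_columns:
            raise InputError(f"column {col!r} not found in gene table")
    return {
        g.gene_id: call_deg(_num(g.attrs.get(fc_col)), _num(g.attrs.get(padj_col)), th)
        for g in table
    }


def _num(value: object) -> float | None:
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None


class AnnotatedPair(NamedTuple):
    """A directed pair with both genes' expression statuses attached."""

    pair: CisNatPair
    target_status: str
    antisense_status: str


def annotate_pairs(
    pairs: PairSet | Iterable[CisNatPair],
    calls: Mapping[str, str] | Iterable[ExpressionCall],
) -> list[AnnotatedPair]:
    """Attach (target status, antisense status) to each directed pair.

    Genes absent from the call set are treated as ``ns``.
    """
    if not isinstance(calls, Mapping):
        calls = {c.gene_id: c.status for c in calls}
    return [
        AnnotatedPair(p, calls.get(p.target_id, NS), calls.get(p.antisense_id, NS))
        for p in pairs
    ]


def crosstab_pairs(
    annotated: Iterable[AnnotatedPair],
) -> dict[tuple[OverlapType, str, str], int]:
    """Count directed pairs per (type, target status, antisense status).

    Only pairs with both statuses in {up, down} are counted; every
    (type, status, status) key is present, zero-filled.
    """
    counts = {
        (t, s1, s2): 0
        for t in OverlapType
        for s1 in _SIGNIFICANT
        for s2 in _SIGNIFICANT
    }
    for ap in annotated:
        key = (ap.pair.type, ap.target_status, ap.antisense_status)
        if key in counts:
            counts[key] += 1
    return counts


def correlated_pair_counts(annotated: Iterable[AnnotatedPair]) -> tuple[int, int]:
    """(positive, negative) correlation counts over unordered pairs.

    Positive: both genes up or both down. Negative: one up, one down.
    Duplicated directed representations (EB/FO duals, HH/TT self-duals)
    are collapsed first, so each locus pair counts once.
    """
    status_of: dict[str, str] = {}
    for ap in annotated:
        status_of[ap.pair.target_id] = ap.target_status
        status_of[ap.pair.antisense_id] = ap.antisense_status
    positive = negative = 0
    for unordered in dedup_unordered([ap.pair for ap in annotated]):
        statuses = sorted(status_of[g] for g in unordered)
        if len(unordered) != 2:  # pragma: no cover - self-pairs are impossible
            continue
        if statuses == [DOWN, DOWN] or statuses == [UP, UP]:
            positive += 1
        elif statuses == [DOWN, UP]:
            negative += 1
    return positive, negative


def inverse_correlated_subset(
    annotated: Iterable[AnnotatedPair],
    types: set[OverlapType] | None = None,
) -> list[AnnotatedPair]:
    """Directed pairs with target down and antisense up.

    Optionally restricted to a subset of geometries (e.g. dropping the
    tail-to-tail group). Sorted deterministically by (target id,
    antisense id, type).
    """
    selected = [
        ap
        for ap in annotated
        if ap.target_status == DOWN
        and ap.antisense_status == UP
        and (types is None or ap.pair.type in types)
    ]
    selected.sort(key=lambda ap: (ap.pair.target_id, ap.pair.antisense_id, ap.pair.type.value))
    return selected
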