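"""Gene-level annotation records.

A gene is represented by its genomic span only: chromosome, strand and a
1-based fully-closed interval ``[start, end]`` (the Ensembl GTF
convention, kept unchanged throughout). Transcript isoforms are out of
scope — antisense-overlap classification here operates on gene spans.

Pass-through attributes (``TPM``, ``fold-change``, ``padj`` ...) ride
along in ``GeneRecord.attrs`` and are never interpreted by the
classifier itself; only the expression module reads them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import InputError

#: canonical strand tokens
PLUS = "+"
MINUS = "-"

_STRAND_ALIASES = {
    "+": PLUS,
    "-": MINUS,
    "−": MINUS,  # unicode minus sign
    "1": PLUS,
    "-1": MINUS,
    "+1": PLUS,
}

#: the required annotation columns of the CSV dialect
CORE_COLUMNS = ("id", "Chr", "Strand", "Start", "End")


def normalize_strand(token: object) -> str:
    """Map a strand token to ``+``/``-``.

    Accepts the ``+``/``-`` and ``1``/``-1`` dialects. Unstranded tokens
    (``.``, ``?``) are rejected: an antisense call is meaningless
    without strand.
    """
    s = str(token).strip()
    try:
        return _STRAND_ALIASES[s]
    except KeyError:
        raise InputError(
            f"invalid strand {token!r}: expected one of +, -, 1, -1"
        ) from None


@dataclass(frozen=True)
class GeneRecord:
    """One gene: location plus pass-through attributes.

    Coordinates are 1-based and inclusive on both ends. On the plus
    strand the transcription start site (TSS) is ``start``; on the
    minus strand it is ``end``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    name: str | None = None
    biotype: str | None = None
    source: str | None = None
    attrs: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be nonempty")
        if self.strand not in (PLUS, MINUS):
            raise InputError(
                f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}"
            )
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id!r}: Start ({self.start}) > End ({self.end})"
            )
        if self.start < 1:
            raise InputError(f"gene {self.gene_id!r}: Start must be >= 1")


class GeneTable:
    """An ordered collection of :class:`GeneRecord` with unique gene ids.

    ``attr_columns`` is the shared schema of pass-through columns, in
    input order; every record carries values (possibly missing) for
    exactly these columns.
    """

    def __init__(self, records: Iterable[GeneRecord], attr_columns: Iterable[str] = ()):
        self.attr_columns: list[str] = list(attr_columns)
        self._by_id: dict[str, GeneRecord] = {}
        dupes = []
        for rec in records:
            if rec.gene_id in self._by_id:
                dupes.append(rec.gene_id)
            self._by_id[rec.gene_id] = rec
        if dupes:
            shown = ", ".join(sorted(set(dupes))[:10])
            raise InputError(f"duplicate gene_id values: {shown}")

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._by_id.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise InputError(f"unknown gene_id {gene_id!r}") from None

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_id)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame in the id/Chr/Strand/Start/End dialect."""
        rows = []
        for r in self:
            row = {
                "id": r.gene_id,
                "Chr": r.chrom,
                "Strand": r.strand,
                "Start": r.start,
                "End": r.end,
            }
            for col in self.attr_columns:
                row[col] = r.attrs.get(col)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CORE_COLUMNS) + self.attr_columns)
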