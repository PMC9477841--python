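"""Reading gene annotation and writing pair lists and summaries.

Two input dialects are supported:

* Ensembl-style GTF (optionally gzip-compressed). Only rows whose
  feature column is ``gene`` are used; coordinates are kept exactly as
  printed (1-based, inclusive). ``gene_source`` and ``gene_biotype``
  whitelists allow dropping duplicated or non-coding annotation before
  classification.
* A gene CSV with the five required annotation columns ``id``, ``Chr``,
  ``Strand``, ``Start``, ``End``; any further columns (``TPM``,
  ``fold-change``, ``padj`` ...) are carried through untouched.
"""

from __future__ import annotations

import csv
import gzip
import math
import re
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .core import CisNatPair, PairSet
from .errors import InputError
from .records import CORE_COLUMNS, GeneRecord, GeneTable, normalize_strand

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_gtf(
    path: str | Path,
    sources: set[str] | None = None,
    biotypes: set[str] | None = None,
    strip_chr_prefix: bool = False,
) -> GeneTable:
    """Extract gene features from an Ensembl-dialect GTF file.

    Parameters
    ----------
    path
        GTF file, optionally gzipped.
    sources
        If given, keep only genes whose ``gene_source`` attribute is in
        this set (e.g. ``{"ena"}`` or ``{"PomBase"}`` to avoid
        duplicated annotation from merged sources).
    biotypes
        If given, keep only genes whose ``gene_biotype`` is in this set
        (e.g. ``{"protein_coding"}`` for a coding-only analysis).
    strip_chr_prefix
        Remove a leading ``chr`` from chromosome names. Off by default:
        chromosome names are compared as exact strings, so mixed naming
        conventions surface as zero overlaps rather than being silently
        patched.

    Raises
    ------
    InputError
        On a malformed line (named by line number) or when gene ids are
        still duplicated after filtering (duplicate annotation should
        be resolved with a ``sources`` whitelist, not silently).
    """
    records: list[GeneRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand_s, _frame, attr_s = fields
            if feature != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise InputError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            attrs = dict(_GTF_ATTR.findall(attr_s))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise InputError(f"{path}: line {lineno}: gene row without gene_id")
            source = attrs.get("gene_source")
            biotype = attrs.get("gene_biotype")
            if sources is not None and source not in sources:
                continue
            if biotypes is not None and biotype not in biotypes:
                continue
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            try:
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=normalize_strand(strand_s),
                        start=start,
                        end=end,
                        name=attrs.get("gene_name"),
                        biotype=biotype,
                        source=source,
                    )
                )
            except InputError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from None
    return GeneTable(records)


def read_gene_csv(path: str | Path, strip_chr_prefix: bool = False) -> GeneTable:
    """Read a gene table CSV (``id,Chr,Strand,Start,End`` + pass-through).

    Column order of the extras is preserved as ``attr_columns``.
    Strand accepts the ``+``/``-`` and ``1``/``-1`` dialects.
    """
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CORE_COLUMNS if c not in header]
        if missing:
            raise InputError(f"{path}: missing required column(s): {', '.join(missing)}")
        attr_columns = [c for c in header if c not in CORE_COLUMNS]
        records = []
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            try:
                start, end = int(row["Start"]), int(row["End"])
            except (TypeError, ValueError):
                raise InputError(
                    f"{path}: row {rownum}: non-integer Start/End "
                    f"({row.get('Start')!r}, {row.get('End')!r})"
                ) from None
            chrom = row["Chr"]
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            try:
                records.append(
                    GeneRecord(
                        gene_id=row["id"],
                        chrom=chrom,
                        strand=normalize_strand(row["Strand"]),
                        start=start,
                        end=end,
                        attrs={c: _coerce(row.get(c)) for c in attr_columns},
                    )
                )
            except InputError as exc:
                raise InputError(f"{path}: row {rownum}: {exc}") from None
    return GeneTable(records, attr_columns)


def _coerce(value: object) -> object:
    """Parse numeric-looking attribute strings; empty string -> NaN."""
    if value is None or value == "":
        return math.nan
    try:
        f = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return value
    return int(f) if f.is_integer() and "." not in str(value) and "e" not in str(value).lower() else f


def write_gene_csv(table: GeneTable, path: str | Path) -> None:
    """Write a GeneTable back to the CSV dialect (round-trip safe)."""
    table.to_frame().to_csv(path, index=False)


def pairs_to_frame(
    pairs: PairSet | Iterable[CisNatPair],
    table: GeneTable,
    extra: Mapping[CisNatPair, Mapping[str, object]] | None = None,
    include_provenance: bool = False,
) -> pd.DataFrame:
    """Tabulate directed pairs: target columns, ``as_``-prefixed partner
    columns, then ``Type``.

    Row order is deterministic: target chromosome, target start, target
    gene id, then type label. ``extra`` attaches additional per-pair
    columns (e.g. expression statuses).
    """
    cols = list(CORE_COLUMNS) + list(table.attr_columns)
    rows = []
    for pair in pairs:
        t, a = table[pair.target_id], table[pair.antisense_id]
        row: dict[str, object] = {}
        for gene, prefix in ((t, ""), (a, "as_")):
            row[prefix + "id"] = gene.gene_id
            row[prefix + "Chr"] = gene.chrom
            row[prefix + "Strand"] = gene.strand
            row[prefix + "Start"] = gene.start
            row[prefix + "End"] = gene.end
            for c in table.attr_columns:
                row[prefix + c] = gene.attrs.get(c)
        row["Type"] = pair.type.value
        if include_provenance and isinstance(pairs, PairSet):
            row["Pass"] = pairs.provenance_of(pair)
        if extra is not None:
            row.update(extra.get(pair, {}))
        rows.append(row)
    columns = cols + ["as_" + c for c in cols] + ["Type"]
    if include_provenance and isinstance(pairs, PairSet):
        columns.append("Pass")
    if extra:
        seen = set(columns)
        for vals in extra.values():
            columns += [c for c in vals if c not in seen]
            seen.update(vals)
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        frame = frame.sort_values(
            ["Chr", "Start", "id", "Type"], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def write_pairs_csv(
    pairs: PairSet | Iterable[CisNatPair],
    table: GeneTable,
    path: str | Path,
    include_provenance: bool = False,
) -> None:
    """Write the directed pair list as CSV (see :func:`pairs_to_frame`)."""
    pairs_to_frame(pairs, table, include_provenance=include_provenance).to_csv(
        path, index=False
    )


def write_summary_csv(summary: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    """Write the per-type gene-count summary (rows any, EB, FO, HH, TT)."""
    frame = pd.DataFrame(
        [
            {"Type": label, "gene_count": int(vals["gene_count"]), "percentage": vals["percentage"]}
            for label, vals in summary.items()
        ],
        columns=["Type", "gene_count", "percentage"],
    )
    frame.to_csv(path, index=False)
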