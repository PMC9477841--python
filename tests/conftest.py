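from __future__ import annotations

import pytest

from cisnat import FixtureSpec, GeneRecord, GeneTable, OverlapType


def gene(gene_id, strand, start, end, chrom="chr1", **kw) -> GeneRecord:
    return GeneRecord(gene_id, chrom, strand, start, end, **kw)


@pytest.fixture
def containment_table() -> GeneTable:
    """One minus-strand gene inside one plus-strand gene."""
    return GeneTable([gene("inner", "-", 100, 200), gene("outer", "+", 50, 250)])


@pytest.fixture
def mixed_spec() -> FixtureSpec:
    """A small fixture with every slot kind represented."""
    return FixtureSpec(
        n_chromosomes=3,
        n_background_genes=20,
        planted={OverlapType.EB: 2, OverlapType.FO: 2, OverlapType.HH: 3, OverlapType.TT: 3},
        n_same_strand_overlaps=4,
        n_identical_span_pairs=2,
        seed=11,
    )


def write_gtf(path, rows):
    """Write minimal Ensembl-dialect GTF lines.

    Each row: (chrom, feature, start, end, strand, attrs-dict).
    """
    lines = ["#!genome-build test"]
    for chrom, feature, start, end, strand, attrs in rows:
        attr_s = " ".join(f'{k} "{v}";' for k, v in attrs.items())
        lines.append(
            "\t".join(
                [chrom, "test_source", feature, str(start), str(end), ".", strand, ".", attr_s]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
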