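# cisnat

Identification and classification of **cis-natural antisense transcript
(cis-NAT) pairs** from gene-level genome annotation, with
differential-expression crosstabs over the resulting pairs.

A cis-NAT is a transcript produced from the same locus as a partner gene
but from the opposite DNA strand, overlapping the partner by at least
one base. Such sense/antisense pairs (e.g. *Xist*/*Tsix*,
*KCNQ1*/*KCNQ1OT1*) frequently regulate each other, and the geometry of
the overlap constrains the possible mechanism. `cisnat` is for
transcriptomics researchers who have a gene annotation (Ensembl-style
GTF, or any gene table with coordinates) and, optionally, a processed
differential-expression table, and who want every antisense pair in the
genome classified and cross-tabulated against expression changes —
without any read-level processing.

## The classification

Genes are treated as 1-based, fully-closed genomic intervals. For a
target gene spanning `[S, E]`, a candidate on the **opposite strand** of
the **same chromosome** with span `[a, b]` and at least one shared base
is classified by four screening conditions:

| Type | Name            | Condition (plus-strand target)  | Geometry |
|------|-----------------|---------------------------------|----------|
| EB   | embedded        | `S ≤ a` and `b ≤ E`             | antisense unit inside the target unit |
| FO   | fully-overlapped| `a ≤ S` and `E ≤ b`             | antisense unit covers the target unit |
| HH   | head-to-head    | `a < S ≤ b < E`                 | overlap at the two 5′ ends (divergent) |
| TT   | tail-to-tail    | `S < a ≤ E < b`                 | overlap at the two 3′ ends (convergent) |

For a minus-strand target the HH and TT interval forms swap (TSS and
TTS exchange ends). In TSS/TTS terms, the FO screen of a minus-strand
target spanning 102,503,972–102,526,860 is exactly

```
(AS-TSS ≤ 102,503,972) & (102,526,860 ≤ AS-TTS)
```

where AS-TSS/AS-TTS are the candidate antisense gene's transcription
start and termination sites. Containment uses non-strict inequalities
and the partial-overlap types use strict outer inequalities, so the
four conditions cover every overlap geometry and only identical spans
carry two labels (both EB and FO).

Every unordered overlapping pair has **two directed representations**
with dual types (EB↔FO, HH↔HH, TT↔TT); the extraction returns both, and
`dedup_unordered` collapses them when counting distinct loci.

Expression statuses are called per gene as `up` (padj < α and fold
change ≥ up threshold), `down` (padj < α and fold change ≤ down
threshold) or `ns`, then directed pairs are counted per
(type, target status, antisense status), and concordant/discordant
pair totals are reported over deduplicated unordered pairs.

## Worked example

Simulate a small genome with planted overlap geometries and planted
expression calls, then recover them:

```sh
cisnat simulate --seed 7 --planted EB=2,FO=1,HH=2,TT=1 \
    --profile up-up=2,down-up=1 --background 20 --out-dir demo
cisnat classify --csv demo/genes.csv --out demo/pairs.csv
cisnat summarize --csv demo/genes.csv
cisnat crosstab --csv demo/expression.csv --out-dir demo/xt
```

This prints (logs to stderr, tables to stdout/files):

```
INFO seed=7: wrote genes.csv (32 genes), expression.csv, truth.csv to demo
INFO found 12 directed pairs (EB=3, FO=3, HH=4, TT=2)
Type,gene_count,percentage
any,12,37.5
EB,3,9.375
FO,3,9.375
HH,4,12.5
TT,2,6.25
INFO correlated unordered pairs: 2 positive, 1 negative
```

The 6 planted unordered pairs appear as 12 directed pairs because each
is reported from both genes' perspectives (the one planted FO pair is
the same locus pair as one of the three EB rows, seen from the other
gene). `summarize` counts *genes* possessing each cis-NAT type, with
percentages over all 32 genes. Of the three planted expression
combinations, two are concordant (`up-up`) and one discordant
(`down-up`), which is what `crosstab` reports after collapsing dual
representations. `demo/xt/inverse_correlated.csv` lists the
target-down/antisense-up directed pairs with both genes' fold-change
and padj columns, ready for external heatmap drawing.

For real data, start from an Ensembl GTF instead:

```sh
cisnat summarize --gtf Mus_musculus.GRCm39.gtf.gz
cisnat classify --gtf Schizosaccharomyces_pombe.gtf.gz --sources PomBase --out pairs.csv
cisnat crosstab --csv deseq2_results.csv --alpha 0.05 --up-fc 2 --down-fc 0.5 --out-dir xt
```

Only rows with feature `gene` are used; `--sources` whitelists
`gene_source` values when an annotation merges databases and would
otherwise contain duplicated gene models, and `--biotypes`
(or `summarize --protein-coding`) restricts by `gene_biotype`.

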