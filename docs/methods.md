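# Methods

## Model

`cisnat` operates on gene spans, not transcript isoforms: each gene is
one 1-based, fully-closed genomic interval `[start, end]` with a
chromosome and a strand, exactly as printed in the `gene` rows of an
Ensembl GTF. The transcription start site (TSS) is the 5′ end of the
span (`start` on the plus strand, `end` on the minus strand) and the
transcription termination site (TTS) the 3′ end. Two genes form a
cis-NAT pair when they share a chromosome, sit on opposite strands and
their closed intervals share at least one base — a single shared
coordinate counts, per the closed-interval convention.

Each *directed* pair (target, antisense partner) is labelled by one of
four screening conditions on the candidate interval `[a, b]` against
the target interval `[S, E]`:

* **EB** (embedded): `S ≤ a` and `b ≤ E`
* **FO** (fully-overlapped): `a ≤ S` and `E ≤ b`
* **HH** (head-to-head): `a < S ≤ b < E` for a plus-strand target, and
  the mirrored form `S < a ≤ E < b` for a minus-strand target
* **TT** (tail-to-tail): the other partial form, swapping with HH when
  the target strand flips

Containment is non-strict; the partial types are strict on the outer
ends so containment is never double-reported as HH or TT. Enumerating
the orderings of the four interval ends shows the four conditions
cover every opposite-strand overlap, assigning exactly one label
except for identical spans, which satisfy both containment conditions
and are deliberately emitted twice (as EB and as FO). An equivalent
formulation used as the independent test oracle: a partial overlap is
HH when both genes' 5′ ends, and neither 3′ end, fall inside the
shared region, and TT for the 3′ analogue.

The extraction runs in both directions, so every unordered locus pair
yields two directed rows with dual types (EB↔FO, HH↔HH, TT↔TT). This
redundancy is intentional — per-type crosstabs are conventionally
presented over directed pairs — and `dedup_unordered` collapses it
where distinct loci are wanted (the concordant/discordant totals).
Whether per-type gene summaries should count a gene in the target role
or in either role is genuinely open; `summarize_types` counts the
target role (the "any" column is identical either way, by duality).

## Implementation

Genes are indexed in one `intervaltree` per (chromosome, strand);
each target queries the opposite-strand tree of its own chromosome, so
work scales with the number of actual overlaps rather than with all
gene pairs. The result is required (and property-tested) to set-equal
the brute-force all-pairs classification. Pass provenance (type and
strand direction, e.g. `FO, minus-to-plus`) is retained per pair and
exported on request.

Pair-list CSV rows are ordered by target chromosome, target start,
target id, then type label (a stable mergesort), making outputs
byte-reproducible. Chromosome names are compared as exact strings; an
optional flag strips a `chr` prefix, but mixed naming is otherwise
left visible as zero overlaps rather than silently patched. Strand
tokens `+`/`-` and `1`/`-1` are normalized; unstranded features are
rejected because an antisense call is meaningless without strand.
Duplicate gene ids after filtering are an error, not a silent dedup —
merged annotation sources should be resolved explicitly with a
`gene_source` whitelist.

## Expression calls

A gene is `up` when `padj < α` and fold change ≥ `up_fc`, `down` when
`padj < α` and fold change ≤ `down_fc`, else `ns`. Defaults:
`α = 0.05`, `up_fc = 1.5`, `down_fc = 0.67` (linear scale); a stricter
twofold contrast is `--up-fc 2 --down-fc 0.5`. Thresholds are always
stated on the linear scale; with `fc_scale="log2"` the data column is
converted via `2^x` before comparison. Missing fold change or padj
(as DESeq2 emits for low-count or outlier genes) always calls `ns` —
treating NA as significant would be wrong. Genes absent from the call
set are likewise `ns`. The up/down labels are contrast-agnostic:
in an allele-bias contrast they read as maternally/paternally biased
expression.

Crosstabs count directed pairs whose both statuses are significant,
keyed by (type, target status, antisense status); pair duality implies
`count(EB, s1, s2) = count(FO, s2, s1)` and symmetric HH/TT entries,
which the tests assert. Concordant/discordant totals are computed over
unordered deduplicated pairs — both EB/FO duals and HH/TT self-duals
collapse, since counting the same locus pair twice would double the
totals. The inverse-correlation export keeps directed pairs with
target `down` and antisense `up`, optionally restricted by type (the
convergent tail-to-tail group is commonly omitted from downstream
heatmaps and the default export drops it).

## Synthetic fixtures

The generator emulates the *shape* of processed annotation +
differential-expression inputs: a multi-chromosome, two-strand gene
set with planted overlap geometries and planted up/down/ns calls. It
places content in disjoint 2 kb slots (20 bp apart) so nothing
overlaps across slots; a slot hosts a planted pair of a requested
geometry, an identical-span pair, a same-strand overlap decoy, or a
background gene. Planted geometries keep ≥ 2 bp margins at every
boundary, so coordinate ties are exercised only by the explicit
identical-span option. Defaults (3 chromosomes of 1 Mb, 30 background
genes, 3 pairs per geometry) are sized for instantaneous generation;
the acceptance-level property runs use 300 genes over 5 chromosomes,
large enough that the interval-index and brute-force paths disagree if
either is wrong, and small enough to compare them exactly, many times,
in seconds. All randomness flows from one seeded numpy generator
(expression values use seed+1), with the seed recorded in the run log.

What the fixtures do **not** emulate: real gene-length and spacing
distributions, nested overlap clusters spanning many genes, transcript
isoform structure, and count-level noise (statuses are planted at the
processed-table level, since the tool consumes processed tables).
Passing tests therefore demonstrate correctness of the classification
and accounting logic, not robustness to annotation quirks of any
particular genome build.

## Scope and limitations

Published dataset-scale figures (per-species percentages of
cis-NAT-bearing genes, genome-wide pair counts, DEG counts from
specific RNA-seq contrasts) depend on specific Ensembl releases and
sequencing archives downloads and are database-version-dependent; the
package reproduces the method, and its property suite replaces those
figures at desk scale. The pipeline starts from processed tables:
read trimming, alignment, quantification and differential testing are
upstream of this package, as are enrichment analysis and all plotting.
No promoter-proximal "non-overlapping antisense" mode is implemented —
the classifier requires ≥ 1 shared base.
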