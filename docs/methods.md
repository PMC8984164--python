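# Methods

`cnvmap` analyses the landscape of small (< 3 Mb) copy-number variants
(CNVs) called in euploid products of conception, the setting where pooled
call tables from one institution plus published cohorts are the only
available data. This note records the models and procedures the package
implements, the choices that were genuinely open, and what the bundled
synthetic cohort does and does not establish.

## Coordinate and vocabulary model

All intervals are 0-based half-open internally; conversion from 1-based
inclusive sources (call tables, GTF, DGV-style flat files) happens once,
at the I/O boundary. Chromosome names are normalised to the UCSC
`chr`-prefixed convention, with lookups tolerating bare names. CNV
direction is a trichotomy {gain, loss, unknown}; source-study labels
(dup/duplication, del/deletion, NA, ...) map through an explicit,
user-extensible synonym table, because pooled studies never share one
vocabulary. Readers never drop rows silently: every input row is either a
record or a reject with a reason, and `rows == records + rejects` is a
tested invariant.

## Inclusion and CNVR construction

Calls are kept when `min_size <= size < max_size`, defaults 0 and
3,000,000 bp. The cap is strict: a 3.0 Mb call is excluded, matching the
"less than 3 Mb" inclusion rule, while the default floor is 0 because
published calls in such pools go below any single laboratory's reporting
threshold (which applies per source, configurable).

A CNVR (copy-number variant region) is the collapse of calls identical in
(chromosome, start, end, direction) across cases — the most conservative
reading of removing "the same" CNV observed in different cases. Support,
contributing samples and per-source provenance are retained.
Unknown-direction calls deduplicate like any other, with direction in the
key. An optional single-linkage relaxation (reciprocal overlap >= 0.99
within a direction) exists for cross-platform breakpoint wobble; it is
off by default because it changes the estimand. Deduplication is
idempotent, order-invariant, and conserves `sum(support) == n_records`
(property-tested).

Euploidy screening is an input contract: callers supply euploid cases
only, as karyotype exclusion happens upstream of any call table.

## Reported/unreported classification

A CNVR is *reported* in a reference catalog (a DGV-style set of variants
observed in healthy individuals) when some catalog variant on the same
chromosome has reciprocal overlap strictly greater than 0.75 —
`min(|A∩B|/|A|, |A∩B|/|B|) > 0.75` — and compatible direction (gain~gain,
loss~loss; catalog `gain+loss` entries match either). Strict inequality
follows the "more than 75%" rule; the exactly-0.75 configuration is a
tested boundary case, and a `strict=False` switch enables `>=` for
sensitivity analyses. Classification is pairwise against single catalog
variants (no unions of partial matches) and happens at CNVR level, after
deduplication. Unknown-direction CNVRs cannot satisfy the direction rule
and are flagged `not_evaluable` rather than counted unreported. The
production classifier uses per-chromosome interval trees; tests require
exact agreement with an all-pairs brute-force oracle.

## Chromosomal distribution and window densities

Per-chromosome counts are split gain/loss/unknown and ordered
chr1..chr22, chrX, chrY. The genome track assigns overlapping CNVs to
distinct lanes by first-fit interval colouring; plots are by-products and
never an analysis surface.

The pericentromeric/sub-telomeric density statistic slides a 5 Mb window
in 0.5 Mb steps through a 9 Mb flank at four anchors per chromosome: the
two telomeres (positions 0 and L) and the two centromere edges. Windows
are anchored at centromere *edges*, not the midpoint, so the flanks
exclude the centromere body — which is assembly gap anyway, and would
only inflate the gap correction. With the defaults each flank carries
`floor((9 − 5)/0.5) + 1 = 9` windows. Windows crossing a chromosome end
(acrocentric-like short arms) are clipped and flagged, not silently
shortened; chromosomes shorter than one window are skipped with a
warning.

Per window, the density is the fraction of *un-gapped* bases covered by
at least one CNV in the pooled set: union coverage, never double-counting
a base, computed for gains, losses and all calls separately. Fully gapped
windows have an undefined fraction, are flagged, and are excluded from
cross-chromosome aggregation. How to aggregate across chromosomes per
offset is genuinely open (mean of per-window fractions vs pooled base
counts), so both columns are emitted. Interval arithmetic is tested for
exact equality against a per-base boolean-mask oracle on 100 kb synthetic
chromosomes.

## Gene content, catalogs, recurrence

CNVR–gene intersection counts any overlap (>= 1 bp, half-open semantics:
adjacency is not overlap), with a `min_overlap_bp` option for sensitivity
analyses. A gene hit by k CNVRs yields k hits; biotype tallies count each
distinct gene once. Because a two-way protein-coding/noncoding split
cannot absorb pseudogene classes cleanly, the full biotype table is
reported with a three-way grouping (protein_coding / noncoding / other),
the noncoding class list being explicit and configurable.

Phenotype (knock-out consequence) and tissue-expression catalogs are
consumed as flat per-gene files keyed by symbol, matched case-sensitively.
Genes absent from a catalog are `uncataloged` — never assumed phenotype-
negative. The funnel reports: genes with any catalogued phenotype; the
embryonic-lethal/abnormal-embryo subset; the abnormal-placenta subset;
placenta-expressed genes. Funnel monotonicity is tested.

Recurrence ranks cytobands by the number of *distinct samples* carrying
an overlapping CNV (a sample with two CNVs in one band counts once),
descending, ties by band name; per-band gain/loss splits and contributing
size ranges are reported. Records without sample ids each count as their
own case, with a warning.

## Over-representation analysis

For a universe of N genes, a term with K members in the universe and a
query of n genes with k in the term, the p-value is the hypergeometric
upper tail P[X >= k] (computed via `scipy.stats.hypergeom.sf`, which is
stable in log space; verified against exhaustive enumeration for
N <= 20). The universe defaults to all protein-coding genes in the
supplied annotation and is shared across the gains-only, losses-only and
combined runs so rows stay comparable. The significance flag defaults to
raw p < 0.05; Benjamini–Hochberg adjusted p-values are always emitted,
and `adjust="BH"` switches the flag to the stricter rule. Because the
tail statistic is discrete, the realised null type-I rate depends on
(N, K, n); the calibration check uses N=500, K=50, n=50, where the
realised rate is 0.0483, and verifies by simulation that uniform null
queries reject near the nominal 0.05.

## Synthetic cohort generator

The generator's defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| n_samples / n_cnvs | 442 / 564 | pooled-cohort scale |
| size distribution | log-normal, mu=13.1513, sigma=1.1, truncated to [6 kb, 3 Mb) | solved numerically so the truncated mean is 690.2 kb with a negligible lower tail and ~5% of draws re-drawn at the cap |
| gain_fraction | 349/564 | pooled gain:loss ≈ 2:1 |
| unknown_fraction | 30/564 | pooled uncertain-direction share |
| pericentromeric_bias | 3.0 over 9 Mb flanks | qualitative enrichment near centromeres/telomeres |
| genome | 8 chromosomes x 80 Mb, metacentric | large enough that CNVR gene hits stay a minority of the gene universe (so term over-representation is detectable), small enough to run in seconds |
| cytobands | 8 per arm (~5 Mb) | near-real band scale; wide bands would swamp a planted recurrent band with background hits |
| planted recurrent band | "1p8" (sub-telomeric), 12 samples, 75% gains | a 19p13.3-like hotspot with known membership |
| n_duplicates | 85 | exact cross-sample duplicates, so CNVR count = 564 − 85 = 479 |
| reported_fraction | 0.52 | reference catalog covers about half the evaluable CNVRs |

One root seed spawns independent sub-streams (genome, cohort, reference,
annotation) via `numpy.random.SeedSequence`, so identical configurations
give byte-identical files and stages can be regenerated independently.

Reference-set construction samples exactly
`round(reported_fraction x n_evaluable)` CNVRs as intended-reported and
emits for each a matching-direction variant shrunk 10% per flank
(reciprocal overlap 0.80). Half of the remaining CNVRs receive a decoy
failing the rule: opposite direction at identical coordinates, or same
direction shifted 60% of the length (overlap 0.4). Because synthetic
CNVRs overlap each other, a variant planted for one CNVR can incidentally
satisfy the rule for a neighbour; the recorded truth status is therefore
recomputed per CNVR against the finished catalog with an independent
all-pairs sweep (intended assignments are kept alongside), so the truth
file is always consistent with the emitted files by construction.

The planted gene-set term draws 30 of its 40 members from protein-coding
genes actually overlapped by a CNVR (the eventual query) and the rest
from unhit genes; decoy terms are uniform draws from the coding universe.

What the generator does *not* emulate: array probe-level signal and
platform-specific breakpoint uncertainty, mosaicism, maternal-cell
contamination, aneuploidy, realistic gene/band size heterogeneity, and
real DGV allele frequencies. Passing the planted-recovery tests therefore
shows the pipeline's interval logic, accounting and statistics are
correct — not that any biological conclusion about real cohorts follows.

## Numerical and degenerate-input choices

- Reciprocal overlap of intervals on different chromosomes is 0 by
  contract, not an error.
- Best reference match ties break by smallest reference start, then
  lexicographic id — fully deterministic outputs.
- Region ids are `chrom:start-end:type`, so re-runs and re-sorts are
  stable; all tables are sorted on deterministic keys.
- Empty cohorts propagate as empty tables plus warnings, never crashes.
- BH adjustment uses the standard step-up `min_{j>=i}(m p_(j) / j)`
  clipped at 1, over the family of tested terms only (terms with K = 0
  in the universe are not tested).

## Problem sizes

Default verification runs use the full-size synthetic bundle
(564 calls, 640 Mb genome, 600 genes, 21 terms), which completes in
well under a minute including the 1,000-replicate null calibration;
per-base oracle checks use 100 kb chromosomes where a boolean mask per
base is exact and cheap.

## Known limitations

- Exact-coordinate deduplication undercounts recurrence across platforms
  with breakpoint wobble; the reciprocal-overlap relaxation exists but
  changes the CNVR definition and is off by default.
- Reported/unreported status depends on the supplied reference catalog
  version; no frequency weighting or pathogenicity scoring is attempted.
- The ORA has no GO-graph propagation and no gene-length or CNV-size
  bias correction; published term lists from any specific cohort are not
  reproduction targets.
- Published pooled tables of this kind can carry internal
  inconsistencies (text vs table totals); the package reproduces
  whatever its inputs contain and only enforces the arithmetic
  identities.
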