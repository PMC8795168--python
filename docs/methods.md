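# Methods

## Problem setting

Two variant-calling pipelines process the same targeted-sequencing data: a
primary ("commercial") pipeline whose output drove the original diagnosis,
and a secondary in-house pipeline used for reanalysis. The package answers
three questions about them: how do their call sets differ (overall, by
variant type, by genomic region, and within the clinically relevant subset);
does the secondary pipeline recover the causal variants the primary one
already established; and, for unsolved cases, which secondary-pipeline calls
deserve analyst review first.

## Variant model and normalization

A call is reduced to a `NormalizedVariant`: one alternate allele, trimmed
and left-aligned, with its call-quality metrics. Normalization splits
multiallelic records, trims shared trailing bases (extending left with the
preceding reference base whenever an allele would empty, i.e. the vt/bcftools
algorithm), then trims shared leading bases. At chromosome position 1, where
no left anchor exists, the last trimmed base is restored and shifting stops,
which reproduces the VCF convention for events at the contig start. The unit
suite checks the result against a brute-force oracle that enumerates every
representation producing the same alternate haplotype inside the context
window, and against `bcftools norm` on a small fixture.

Types follow the length rule: SNV iff both alleles are single bases;
everything else is INDEL, with non-trimmable multi-nucleotide substitutions
flagged `mnv` (they are rare and the downstream stratifications only
distinguish SNV/INDEL). A variant's reference *span* is 0-based half-open;
an insertion's span covers its two flanking anchor bases so that "the
breakpoint falls inside the other variant's span" is a plain interval
intersection.

Matching has two modes. `exact` compares `(chrom, pos, ref, alt)` keys.
`overlap_indel` keeps exact matching for SNVs but declares two INDELs the
same variant when their spans share at least one base — the convention
needed when two pipelines emit shift-equivalent representations of the same
indel. Overlap matching is reflexive and symmetric but deliberately not
transitive; set-level accounting therefore reports matched counts per side
(`n_matched_a`, `n_matched_b`), which coincide in exact mode.

Without a reference context, normalization degrades to trim-only and logs a
warning; matching may then miss shift-equivalent INDELs. Chromosome dialects
are unified by stripping a leading `chr`.

## Regions and padding

Target regions are merged, sorted, 0-based half-open intervals (BED
convention; VCF positions are converted on ingest). Padding extends every
interval by `pad_bp` (default 1000) on both sides, clips at zero and
re-merges. Membership is partial-overlap: a variant whose span touches any
interval is inside, so a deletion straddling a target boundary counts even
though its breakpoint lies outside the BED — the discrepancy class that
raw positional comparisons misclassify. Region membership queries use
binary search over the merged interval starts; no interval tree is needed
because the merged representation is disjoint.

## Annotation layer

Per-transcript consequences are parsed from a VEP-style pipe-delimited INFO
field whose format is read from the VCF header (key and dialect
configurable; common field-name aliases are accepted). Region classification
maps Sequence-Ontology terms through a packaged editable TSV
(`reanalyzer/data/so_region_map.tsv`) and resolves multi-term annotations by
the fixed precedence exonic > splicing > utr5 > utr3 > ncRNA > intronic >
upstream > downstream > intergenic > other; unknown terms fall to `other`
with a one-time warning. The precedence order is this package's own choice —
only the category axes are externally fixed — and it is deterministic and
total by construction.

Canonical restriction keeps one annotation per (variant, gene): a variant
canonical in k genes contributes k counting units to the stratified
statistics. Two canonical transcripts of the same gene are tie-broken on the
lexicographically smallest transcript id (determinism over biology; the case
is degenerate in practice).

Clinical relevance: the ClinVar label set must be non-empty and contain only
pathogenic / likely pathogenic / uncertain-significance labels; a VUS-only
variant must additionally have gnomAD POPMAX AF < 0.1. An absent POPMAX
passes — absence from gnomAD implies rarity. "Maximum AF" is taken from the
dedicated annotation field when present, else computed as the maximum over
the available ExAC / 1000G / gnomAD fields.

## Filters

Hard filters and quality filters use strict comparisons exactly as stated
(`DP > 10`, `QUAL > 100`, `QD < 2.0`, ...), and a missing metric never fails
its test (the convention of the caller that produced the thresholds). The
diploidy criterion is approximated as a minimum variant-allele fraction for
heterozygous calls, default 0.2 and configurable: the underlying pipeline's
exact ploidy test is not published, only an example of an 18%-VAF call being
rejected, so this check is flagged approximate and kept out of the
quantitative acceptance surface. All filters are pure functions of the
record; the combined verdict is the order-independent union of failure
reasons.

## Comparison statistics

Counts are compared per category — variant type, and variant type × region
class — over a seeded subsample of 100 samples per pipeline (all samples,
with a warning, when fewer exist). Two tests are computed side by side
because the upstream protocol is ambiguous between them: a two-sided Fisher
exact test on the 2×2 table of summed in-category vs out-of-category counts
(checked in the tests against exact hypergeometric enumeration), and Welch's
t-test on the per-sample counts. Neither is privileged; fold change is
mean(secondary)/mean(primary) over the subsample; zero-variance equal-mean
t-tests report p = 1 and are flagged. The subsampling seed defaults to 42
and is recorded in every result. No multiple-testing correction is applied.
Cohort summaries report mean ± SD per cell with absent cells as zeros.

## Causal audit and percentage conventions

A causal record resolves through its genomic key when present (exact for
SNVs, overlap for INDELs), else through (version-less transcript accession,
HGVS c.) string equality against the annotations; records resolvable by
neither are excluded from the denominator and listed separately. The call
set is restricted to the active target regions first, so a record outside
them reports `outside_regions` rather than `absent_from_calls`. A matched
but filtered call reports the most specific failing class: `low_vaf` before
`hard_filter_fail` before `low_qual_dp`. A homopolymer flag (run of ≥4
identical bases adjacent to the locus) is informational only and never
changes a status.

Detection efficiency truncates at its printed precision (2 decimals) — a
reported efficiency never overstates detection — while diagnostic yield
rounds half-up (1 decimal by default). Both expose the other mode, since
published audit figures mix the two conventions.

## Reanalysis cascade and prioritization

Input is the secondary pipeline's canonical-restricted, quality-passing
call set. Stages, in order: (0) Maximum AF < 0.05 (toggleable — upstream
output is typically pre-filtered to this level already, so the stage is
usually a no-op); (i) every available per-source AF < 0.01 AND
POPMAX AF < 0.01, absent values passing; (ii) differential filtering:
remove variants matching the same sample's commercial VCF, with overlap
matching by default so shift-equivalent INDELs are not falsely retained;
(iii) virtual panel: keep variants with any canonical gene on the panel.
Stage counts are recorded and non-increasing by construction. Stages (i) and
(iii) commute, and (ii) depends only on the commercial set; the fixed order
mirrors the analyst-facing funnel. An enabled panel stage with an empty
panel is an error (a silent empty result would look like a clean case).

Survivors are ordered deterministically: tier 1 = INDELs (any region),
tier 2 = non-exonic SNVs, tier 3 = exonic SNVs — the feature classes the
primary pipeline under-calls — then within tier by ClinVar rank
(pathogenic < likely pathogenic < VUS < none), CADD descending with absent
last, then genomic coordinate. Only the tier rule is externally fixed; the
within-tier order is this package's choice so that analysts see a total,
reproducible ordering. The review export is one TSV row per survivor in
exactly that order and round-trips losslessly.

## Synthetic cohorts: what they emulate, and what they do not

The generator emits paired per-sample call sets on a synthetic ~1.4 Mb
contig with 60 genes × 6 targets of 250 bp. Defaults are the study
conditions used throughout testing: 100 samples, 4000 variants per sample,
12% INDELs, pipeline assignment P(both) = 0.88, P(primary-only) = 0.03,
P(secondary-only) = 0.04, P(padding-only) = 0.05 — padding-only calls are
emitted solely in the secondary pipeline's files, 8–949 bp outside a
target. The allele-frequency model is a mixture (5% absent; otherwise
log-uniform in a rare [1e−6, 0.01) or low-frequency [0.01, 0.05) component)
in which pipeline-unique calls draw the rare component with probability 0.75
versus 0.16 for shared calls: novel calls are rarer, which is what makes a
differential-reanalysis funnel work at all. Under these defaults a
4000-variant sample funnels to ≈990 after the AF stage, ≈280 after the
differential stage and ≈41 after a 9-gene (15%) panel, and the two
pipelines share ≈88% of calls in the padded comparison (≈92.6% restricted
to targets). ClinVar labels are planted at 1%/1%/4%/3%
(P/LP/VUS/benign); 2% of variants carry a second canonical-gene annotation
to exercise the multi-gene counting rule; 1.5% of records receive a QC
failure that violates exactly one filter predicate. Every emitted variant
appears exactly once in a truth table carrying its construction provenance
and expected downstream fate; the acceptance suite requires module outputs
to equal that table exactly.

Planted causal scenarios (one sample each, plus three plain "found"
records): a splice SNV 2–3 bp outside a target, detectable only with
padding; a second-allele exonic deletion in a panel gene, secondary-only,
AF-absent, which must survive the cascade at tier 1; a causal SNV at
VAF = 0.18, missed with reason `low_vaf` when the diploidy check is active;
a low-MQ call missed as `hard_filter_fail`; and a record never called,
missed as `absent_from_calls`.

Deliberate simplifications: variants are emitted already normalized (the
generator runs its raw constructs through the normalizer, so files and truth
agree by construction); non-padding variants are placed inside target
intervals regardless of annotated region class, since region class lives in
the annotation layer, as with real capture designs whose targets span
UTR/intronic flanks; per-sample INDEL spans never overlap unless identical,
so overlap matching cannot join two distinct planted variants; QC injection
sets only the violating metric (a real caller would also set FILTER);
quality metrics are drawn independently of each other and of allele
frequency; there is no linkage, no shared population structure across
samples, no sequencing-error model and no homopolymer-context enrichment of
indel errors. Passing against this generator therefore demonstrates the
correctness of the set arithmetic, filters, audit logic and cascade — not
calling accuracy on real reads, which is out of scope.

## Numerical and engineering choices

Percentage rounding uses decimal arithmetic (no binary-float surprises at
the .5 boundary). Statistics go through scipy (`fisher_exact`,
`ttest_ind(equal_var=False)`); tables through pandas; VCF I/O through
cyvcf2 with a plain-text VCF 4.2 writer that round-trips through the same
reader; FASTA through pyfaidx (or an in-memory reference). All randomness —
generator and subsampling — flows from explicit seeds via
`numpy.random.default_rng`; identical seeds give byte-identical output
files. The acceptance script regenerates everything from scratch at the
study scale in about a minute on one CPU; the test suite uses a 10-sample,
500-variant cohort for integration tests and the full scale only in the
acceptance layer.

## Known limitations

Symbolic alleles, breakends, gVCF blocks and structural variants are
rejected or skipped, not modelled. HGVS matching is string equality on
(transcript sans version, c. notation); no projection or validation.
The diploidy threshold is an approximation of an unpublished criterion.
Overlap matching is not transitive, so "number of common variants" is a
per-side count under that mode. The generator's AF spectrum is tuned to the
reanalysis funnel rather than fit to a population-genetics model.
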