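# Methods

## Problem and data model

A paralogous miRNA family is a set of ≥ 2 hairpin precursors at distinct
genomic loci whose major mature forms are identical in sequence. All
quantities derive from a long-form read-mapping table with one record per
(precursor, read start position within the hairpin, tissue) and a read
count, the shape of miRBase-style deep-sequencing annotation reports.
Coordinates are 1-based inclusive within the hairpin (miRBase convention);
reads are assumed pre-filtered to perfect matches, and multi-mapping reads
are counted once per hairpin record as given in the input — the table
itself is the unit of evidence, no realignment or fractional reassignment
is attempted.

## Arm assignment and quantification

Per precursor, the start position with the highest read count summed over
tissues defines the major (guide) form and its arm; the highest-count
start on the opposite arm defines the minor (passenger) form. Arms are
taken from the mature annotation when present, otherwise the hairpin
midpoint splits them. Ties at the argmax resolve to the 5′-most position
(deterministic). Precursor-level expression sums all starts; major/minor
levels take the designated start's per-tissue counts. Normalization is
reads per million of the tissue's library total; by default the total is
the table's own per-tissue sum, with an override accepted because real
library totals include the full small-RNA complement, not only the
entities in the table. Arm-usage ratios (major total / minor total, with
∞ encoding an absent minor) are reported for pairs whose major exceeds 50
reads strictly; a config switch applies the filter to major+minor combined
instead, since both filter universes are defensible readings of the
source material and they are not reconciled there.

## Tissue coexpression score

With M the entity × tissue count matrix, T_i its row totals and Q_j the
per-tissue fraction of all reads (computed from the full universe matrix:
precursors, majors and minors), the tissue specificity is

    Z_ij = max(0, (M_ij − T_i·Q_j) / sqrt(T_i·Q_j·(1−Q_j)))

the one-sided binomial enrichment z-statistic: under proportional
allocation of an entity's T_i reads across tissues (reads ~ Binomial(T_i,
Q_j)), Z_ij counts standard deviations of excess. Truncation at zero makes
under-represented tissues carry no specificity, and Z_ij = 0 whenever
M_ij = 0. The pair score S_j = Z_major,j · Z_minor,j is therefore ≥ 0,
exactly 0 when the minor form has no reads, and equivariant under tissue
permutation. This algebra follows the EST/read-count tissue-specificity
lineage of methods the approach descends from; it is isolated in
`coexpression.z_matrix`/`specificity_z` so an alternative transcription is
a one-line swap.

Selection: entities with total reads ≤ 50 (strict) are excluded; scores
are ranked globally across all pair × tissue combinations (per-family and
per-tissue scoping exist as options) and the top decile kept —
ceil(0.1·N) highest scores, ties at the cutoff all included, zero scores
never selected since a zero score carries no coexpression evidence.
Percentile rank uses "≥ this score" counting.

Fisher screen: for sibling minors A, B and tissue j the 2×2 table is
[[A_j, A_elsewhere], [B_j, B_elsewhere]]; the two-sided p sums
hypergeometric point probabilities of tables as likely or less likely than
observed (point-probability convention, 1e-7 relative tie guard, the same
convention scipy uses). A member passes in tissue j when p < 0.05 against
every sibling. No multiple-testing correction is applied by default (raw
p < 0.05 matches the source procedure); a Benjamini–Hochberg option
exists. All-zero tables return p = 1 and are flagged degenerate. The
scalar path wraps `scipy.stats.fisher_exact`; a vectorized path groups
tables by margins so each distinct hypergeometric distribution is
evaluated once, making exhaustive sweeps affordable — both paths are
cross-checked against exact integer-arithmetic enumeration in the tests.

The contributor call per family × tissue is the highest-scoring member
that is both top-decile and Fisher-passing. Families whose members share
identical minor sequences are flagged indistinguishable and never called
(their evidence cannot separate members in principle). An optional Pearson
pre-filter excludes members whose major and minor expression are not
significantly positively associated.

## Association screens

Pearson R with the exact two-sided p under bivariate normality
(t-transform, n−2 df) via `scipy.stats.pearsonr`. Defaults: α = 0.01 for
the major/minor and cluster screens, α = 0.05 for host-gene checks;
normalized (RPM) values by default with a raw-count option, since which
scale the original screens used is not stated. Constant vectors leave R
undefined; such pairs are flagged and excluded from significance tallies.
Summary fractions report round(100 · significant-positive / total).

## Tissue patterns (SPM/CTM)

SPM_j = x_j / ‖x‖ (cosine between the expression vector and the unit axis
of tissue j); CTM of a tissue subset = ‖x restricted to the subset‖ / ‖x‖.
Both are invariant to global rescaling; squared SPMs sum to 1. Calls:
specific if any SPM > 0.9 (priority), else selective if ≥ 2 tissues have
SPM > 0.5 and their joint CTM exceeds 0.9, else none. The thresholds are
fixed by the source procedure; the metric algebra is the cosine/projection
form of the pattern-gene framework it cites, isolated in one function each
(`tissue_pattern.spm`, `tissue_pattern.ctm`) so an alternate transcription
is a one-line swap. Inputs are RPM vectors; all-zero vectors are
undefined and flagged.

## Genomic clusters and host genes

Single-linkage chaining of same-chromosome, same-strand precursor loci
with gap = next start − previous end < 5000 bp (strict; the gap convention
matches distance between nearest interval ends). All unordered
within-cluster pairs are emitted (n·(n−1)/2 per cluster). Host-gene
relationships are supplied by an input mapping, not inferred from
transcript overlap — inferring them would require transcript models that
are out of scope.

## qPCR statistics

Comparative-CT: ΔCt = Ct_target − Ct_reference per tissue and replicate
(reference U6 snRNA for miRNA, 18S rRNA for mRNA), ΔΔCt against a
calibrator tissue, fold = 2^(−ΔΔCt). The calibrator defaults to the tissue
with the lowest mean ΔCt (highest expression) since none is named by the
source procedure and folds are only interpreted relatively. Preferential
tissues: one-way ANOVA on replicate-level −ΔΔCt (log2 scale for variance
stability); if p < 0.05, Tukey HSD is run and the flagged set is the
largest prefix of tissues by descending mean in which every member beats
every non-flagged tissue significantly — a prefix, so that several
jointly elevated tissues (not separable from one another) can be flagged
together, matching how multi-tissue preferential profiles are starred.

## Synthetic data generator

The generator emulates the statistical structure the pipeline targets, on
a 15-tissue mouse-style compendium by default: 8 two-member paralogous
families (shared 22-nt major mature sequence embedded in random 70-nt
hairpins at start 5 on the 5p arm / 45 on the 3p arm, member-specific
minors differing by 1–2 nt), each member transcribed in one distinct
tissue; 20 singleton precursors (8 tissue-specific, 6 two-tissue-selective,
6 unrestricted) that populate the scoring universe and the pattern
battery; planted genomic clusters (sizes 2 and 3, 2 kb gaps) whose members
share their planted tissue, emulating co-transcription; and host genes
co-regulated with their member's activity.

Parameters with units and defaults: major expression 2000 reads in
expressed tissues (background 2); minor:major ratio 0.05 (within the broad
observed range of arm-usage ratios); isomiR stray reads at 5% of the major
one position 3′ of it; negative-binomial counts with var = m + φ·m²,
φ = 0.05 — single-library technical overdispersion, since each tissue is
one pooled library rather than a set of biological replicates (φ = 0 gives
the Poisson limit; larger values model biological replication); nominal
library size 1e6 reads/tissue, recorded in the truth record and used as
the normalization total (the simulated precursors are a small slice of a
real library, so dividing by the slice's own sum would distort planted
patterns). A minor ratio > 1 plants an arm switch and is rejected unless
explicitly allowed. Ct simulation: preferred tissues get target Ct lower
by log2(fold) cycles (default fold 16), Gaussian well noise σ = 0.25
cycles, 3 replicates, flat reference gene.

What the generator does not emulate: sequence-content and ligation biases,
isomiR 3′-end heterogeneity, multi-mapping ambiguity across family
members, and between-animal biological variance. Passing recovery tests
therefore shows the statistics identify planted structure under idealized
read generation, not that real libraries meet these assumptions.

## Problem sizes and numerical choices

The seeded batteries use 50 generator seeds for contributor/pattern
recovery, 1,000 random fixtures for the zero-read rule, an exhaustive
sweep of all 741,321 2×2 tables with row margins ≤ 40 for the exact test,
10,000 replicates for null-p uniformity, and 2,000 null replicates for the
ANOVA type-I rate — sizes chosen so the whole suite runs in a few minutes
on one CPU while keeping Monte-Carlo standard errors well inside the
asserted tolerances. Degenerate inputs are explicit: empty matrices are
refused for GCT export, all-zero expression vectors are undefined for
SPM/CTM, zero library totals with nonzero counts raise, constant vectors
are excluded from correlation tallies, and all-zero Fisher tables return
p = 1 flagged degenerate.

## Known limitations

The attribution logic needs the minor forms to differ between members;
families with identical major *and* minor sequences are reported
unresolved by design. The score has no closed-form null calibration — the
top-decile rank is a relative screen, not a p-value. Host-gene and cluster
corroboration assume co-transcription, which post-transcriptional
regulation can break. The >50-reads filter is applied as two documented
variants (major-only vs combined) because the two source statements of the
filter differ; results near the threshold depend on the variant chosen.
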