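# Methods

## The model

A miRNA locus is *in-cis dysregulated* when a DNA-level aberration at the
locus itself — copy-number change or promoter-methylation change — is
associated with the expression of the mature miRNA. Two biological
scenarios are scored separately: **activating** (gain or hypomethylation
raising expression, candidate oncogenic miRNAs) and **silencing** (loss or
hypermethylation lowering it, candidate tumor suppressors). Because a
mature miRNA can be encoded at several genomic loci, and arrays measure the
mature transcript, all per-locus analyses run on an expanded matrix in
which each locus carries a copy of its mature miRNA's expression row; this
is what makes family-level redundancy (identical seed, different
chromosomes) visible.

## Stages, parameters and defaults

**Expression normalization.** Detection filter first (miRNAs detected in
fewer than 10 % of samples removed, strict inequality), then per-sample
subtraction of the 90th percentile across remaining miRNAs. The percentile
is the type-7 (linear-interpolation) estimator; both the fraction and the
detection threshold are configurable. The order — filter before
percentile — is a documented choice; with hundreds of miRNAs the percentile
is insensitive to it. When no explicit detection flags exist, non-missing
stands in for detected.

**Copy-number segmentation.** Exact O(n²) dynamic programming minimizes
`sum of within-segment squared errors + gamma * (number of breakpoints)`
per sample and chromosome. Exactness — rather than the pruning heuristics
used for very dense arrays — keeps desk-scale runtimes acceptable and lets
tests compare against brute-force enumeration. γ defaults to 40 (use a
larger value, e.g. 50, for higher-resolution arrays). At the cohort level
the penalty is expressed in units of each sample's noise variance,
estimated robustly as `median(|lag-1 differences|) / (0.6745 * sqrt(2))`,
mirroring the per-sample scaling of the established PCF implementations;
`noise_normalize=False` applies γ to raw SSE. Equal-objective ties break
toward fewer breakpoints, then earlier breakpoints. Missing probes are
dropped per track before fitting. Loci take the mean of the segment whose
probe span (first to last probe bp, inclusive) covers the locus start;
loci outside all spans take the nearest segment's mean. miRNAs are short,
so coverage is decided by the start coordinate alone.

**Aberration calling.** Copy number: gain iff segmented value > +0.1, loss
iff < −0.1, strictly; boundary values are neutral. Methylation: per locus,
the normal-reference median *m* and sample SD (n−1 denominator) define
cutoffs m ± k·SD with k = 2 by default; calls use strict inequalities. A
lower cutoff below 0 disables hypomethylation calls for that locus, and
symmetrically an upper cutoff above 1 disables hypermethylation calls —
degenerate thresholds cannot be exceeded meaningfully by a β value. The
multiplier k is configurable so percent-methylation assays (values in
[0, 100] rescaled to [0, 1]) reuse the same rule. Loci with fewer than two
usable normals are excluded from methylation calling. Under approximately
Gaussian β noise the 2-SD rule miscalls held-out normal-like samples at
roughly 5 % per locus (the test suite asserts ≤ 8 % with a 17-normal
reference).

**Group construction.** For single-axis tests the reference group is every
sample with a non-missing state that is not in the target state — so
losses sit in the reference group of an activating copy-number test; the
partition of patients is binary on the tested axis. For the combined test
the altered group is gain-or-hypomethylated (activating; symmetric for
silencing) and the reference group contains only samples with no
aberration on either axis. Groups below `min_group_size` (default 3) make
the locus untestable for that spec and remove it from that family's BH
denominator.

**Testing and adjustment.** The Wilcoxon rank-sum statistic W is the
mid-rank sum of the altered group. The two-sided p-value is exact
(enumeration of the rank-sum permutation distribution) when the pooled
size is ≤ 20 with no cross-group ties; otherwise a tie-corrected normal
approximation with a signed continuity correction is used, which returns
exactly 1 for identical groups. BH adjustment runs within each of the six
(scenario, category) families across testable loci; significance requires
q < 0.05 *and* the correlation-direction filter: Spearman ρ(copy number,
expression) > 0 for copy-number categories, ρ(methylation, expression) < 0
for methylation categories, and for the combined category every axis that
contributed an altered sample must pass. The direction filter is the
computational stand-in for inspecting expression-versus-aberration plots;
the sign of the correlation is the criterion.

**Driver classes.** A locus significant only in copy-number-category tests
is *copy_number*-driven; only in methylation-category tests,
*methylation*-driven; both single-axis categories, or only the combined
category, *combination*. The effect is *activating*, *silencing*, or
*both* when both scenarios yield significant direction-passing results.

**Replication.** Candidates re-run the scenario/category tests that were
significant in discovery, on whichever axes the replication cohort
measures, at uncorrected p < 0.05 (FDR is reserved for discovery, where
the whole locus set is scanned; replication tests a short pre-specified
list). The aberration type must match and the direction filter must pass.
When two CpG assays cover one promoter, each assay is tested separately
and the larger p-value is reported — a conservative rule. Candidates
absent from the replication expression matrix leave the denominator.

**Family complementarity.** Seed families are defined by identical
nucleotides 2–8 of the mature sequence; the family id is the seed plus the
lexicographically smallest member mature id, making grouping reproducible
under reordering. (Curated family catalogs group by seed region too; the
seed is the testable surrogate.) For families with ≥ 2 in-cis members, a
member's activating state in a patient is gain OR hypomethylation, the
family's overall state is the OR over members, and the summary is the
fraction of patients with overall state true.

**Downstream scans.** Two-level clinical variables (ER, HER2, TP53,
luminal/basal subtype) use the rank-sum test; histological grade uses
Kruskal–Wallis with tie correction and a chi-square p on k−1 df. FDR runs
across loci per variable per cohort; cross-cohort consistency requires
q < 0.05 in both cohorts with concordant direction (direction concordance
is a configurable choice — significance alone is the weaker alternative).
Survival uses a median split of expression: samples strictly below the
median are "low", samples exactly at the median join the low group (a
documented convention; odd cohort sizes make an exact 50/50 impossible),
and the two-group log-rank test uses the standard hypergeometric variance
at tied event times. The miRNA–mRNA screen selects pairs with Spearman
|ρ| > 0.3 over complete cases and keeps those selected with the same sign
in both cohorts. Functional-screen hits: viability values (consumed
already plate-normalized and log2-transformed; plate normalization is
upstream of this package) are hits at |value| > 0.2; lysate-array
endpoints are standardized against the whole screen's mean and SD and are
hits at |z| > 1.96.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 100 tumors and 17 methylation-reference normals; 5
chromosomes × 2,000 copy-number probes; 500 miRNA loci; 10 planted loci
per mechanism (gain, loss, hypomethylation, hypermethylation, combined);
expression shift Δ = 1.5 log2 units in 30 % of tumors per planted locus
over N(0, 0.5) noise; copy-number segments shifted ±0.3 over N(0, 0.15)
probe noise across a ±2 Mb window around the locus; β shifted ∓0.2 over
clipped-Gaussian noise with SD 0.02 around per-locus baselines drawn
U(0.15, 0.75). Five two-member seed families pair a gain-planted locus
with a hypomethylation-planted locus of the same mature miRNA, with
disjoint altered-sample sets — the complementary pattern. Combined loci
split their altered samples half gain / half hypomethylation. Probe tiers
are exercised by making ~8 % of loci intronic with host-gene promoter
probes and ~7 % probe-less (nearest-probe tier); a few "dim" matures
detected in < 10 % of samples exercise the detection filter. mRNA genes,
clinical subgroup effects (one TP53, one grade, one ER target), and an
exponential survival model with uniform censoring and hazard linear in one
prognostic locus's expression feed the downstream scans. Cohort pairs
share one design (loci, mechanisms, families) with independent samples and
noise.

β noise is clipped Gaussian rather than Beta-distributed: the 2-SD calling
rule then has an analytically transparent false-call rate. What the
generator does **not** emulate: tumor-purity dilution, correlated genome-
wide aberration landscapes (each planted segment is independent), batch
effects, probe cross-hybridization, or realistic marginal distributions of
expression. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated noise model, not performance on
real arrays.

## Numerical conventions and degenerate inputs

- Coordinates are 1-based inclusive internally; BED export converts to
  0-based half-open.
- Nearest-probe ties break toward the lower coordinate, then probe id.
- Missing values propagate everywhere; nothing is imputed.
- Exactly-at-threshold values (β at m ± k·SD, copy number at ±0.1) are
  never calls (strict inequalities throughout).
- Spearman correlations require ≥ 3 complete pairs and a non-constant
  vector on both sides; otherwise the quantity is undefined (NaN) and the
  direction check is untestable.
- All-identical pooled samples give rank-sum p = 1; a zero screen SD is an
  error rather than a silent division.
- Every stochastic routine takes an explicit seed; pipelines record the
  seed and all thresholds in the run log.

## Problem sizes used in validation

The test suite validates the segmentation optimizer against brute-force
enumeration on 500 random signals of length ≤ 12, the rank-sum p against
exhaustive enumeration for group sizes ≤ 8 (200 cases), and BH/Spearman
against naive re-implementations. Parameter recovery runs the full
pipeline at the default scale over seeds 1–5; replication uses three
default-scale cohort pairs; null calibration uses twenty cohorts at a
thinned copy-number resolution (200 probes/chromosome, 300 loci) with the
expression–aberration coupling switched off, a scale chosen because the
null behavior of the test statistics does not depend on probe density.

## Known limitations

- The exact O(n²) segmenter is not intended for million-probe arrays; the
  established pruned implementations serve that regime.
- Driver-class labels are a deterministic rule over which test families
  reach significance; loci with near-threshold q values can flip class
  between cohorts.
- The combined-category reference group ("no aberration on either axis")
  shrinks when aberrations are frequent, costing power exactly where
  aberrations are most common.
- Replication of combined-category candidates requires both axes measured
  in the replication cohort; otherwise the candidate is unassessable for
  that category.
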