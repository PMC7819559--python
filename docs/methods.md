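# Methods

`urbmeth` reimplements, as a tested pipeline, the post-alignment analysis of a
two-habitat reduced representation bisulphite sequencing (RRBS) study design:
six urban and six forest individuals, per-cytosine methylation counts from a
Bismark-style aligner, and a companion gene-expression count table from the
same birds. This note records the models, the parameter choices and their
rationale, the numerical decisions, and what the synthetic data do and do not
emulate.

## Site-level differential methylation

Each destranded CpG unit is tested with a logistic regression of read-level
methylation status on habitat. Because habitat is a single binary covariate,
the maximum-likelihood fit is available in closed form — the fitted
probability in each group is the pooled group fraction
`sum(methylated) / sum(total)` — so the likelihood-ratio statistic

```
G = 2 [ ll(m_u, t_u) + ll(m_f, t_f) − ll(m_u + m_f, t_u + t_f) ]
```

(binomial profile log-likelihoods at the group and pooled MLEs) is computed
vectorised across all sites and referred to a chi-square with 1 df. Sites
with no information (all reads unmethylated, or all methylated, in both
groups) are assigned p = 1. No overdispersion correction is applied; with
per-sample binomial noise and no extra between-individual variance this test
is well calibrated (the acceptance battery checks Kolmogorov–Smirnov
uniformity of null p-values), but on real data with biological replicate
variance it will be anticonservative — a known limitation shared with the
default multi-sample logistic test of the methylKit family of tools. A
Fisher-exact alternative on the pooled group counts is available via
`site_test(..., test="fisher")` for sensitivity analysis.

The reported effect size `meth_diff` is the difference of group means of
per-sample methylation fractions, in percentage points (urban − forest). A
site is a DMS when `|meth_diff| > 25` (strict) and `q < 0.01` (strict).

## SLIM q-values

P-values are adjusted with a sliding-linear-model estimate of the null
proportion π0 scaling a Benjamini–Hochberg adjustment: q = π0 · BH(p). The
empirical CDF of the p-values is evaluated on the λ grid 0.05, 0.10, …, 0.95;
a straight line is fitted to every 5-point segment; in the region where only
null p-values remain the CDF is linear with slope π0, so the segment with the
smallest residual variance (the most stable segment) supplies the estimate,
clipped to (0, 1]. Two corners are defined explicitly: with fewer than 100
p-values the estimator is unreliable and the adjustment falls back to plain
BH (π0 = 1, with a warning); a degenerate fit (slope ≤ 0.001, e.g. every
p = 1) falls back to the tail estimator `P(p > 0.5) / 0.5`, which keeps the
identity "all p = 1 → all q = 1". Monotonicity of q in p is enforced after
scaling.

## Permutation null

Genome-wide significance is assessed by permuting the habitat labels of the
twelve individuals and rerunning the entire site-level analysis (test, π0,
q-values, thresholds) in every iteration. Permuting the label vector keeps
the 6/6 balance by construction; labellings are sampled with replacement
(only 924 distinct balanced splits exist, so redraws of the observed split
are legitimate and expected). The default statistic is the number of called
DMSs; the mean |difference| at called sites is available as an alternative.
The p-value uses the add-one formula `(1 + #{null ≥ observed}) / (n_iter + 1)`
so it is never exactly zero. Default 1,000 iterations; the test suite and the
acceptance script run 100 to keep wall-clock time proportionate, which leaves
the minimum attainable p at 1/101.

## CpG islands, shores and gene features

The island detector cuts the genome into non-overlapping 100-bp windows and
computes, per window, the GC fraction and the CpG observed/expected ratio
`N_CG · L / (N_C · N_G)` (defined as 0 when a window has no C or no G;
ambiguous bases count toward window length only). Every stretch of 10
consecutive windows whose *mean* GC ≥ 0.50 and *mean* obs/exp ≥ 0.60 marks
all ten windows as island; the union of marked windows is merged and merged
regions ≥ 200 bp are reported. Averaging over a 10-window stretch, rather
than qualifying each window by its own trailing average, is deliberate: a
trailing-average rule never qualifies the leading windows of an island
(their averages are diluted by upstream background), which caps base-level
recovery of a true island far below what a window-averaged definition
intends. The stretch rule recovers planted islands essentially completely at
the cost of up to ~900 bp of spillover beyond a strong island's edge —
acceptable because shores are 2 kb and thresholds are met with margin only
near real islands. A `per_window=True` switch provides the stricter
window-by-window variant for sensitivity analysis.

Shores are the 2 kb flanks of each island, with bases inside any island
excluded and overlapping shores merged — "flanking" regions should not
double-count island bases, though exclusion is a design choice rather than a
stated rule. Gene features are strand-aware around the 5′ gene start g:
TSS = [g−300, g+50), promoter = [g−3000, g−300) (mirrored on the − strand),
gene body = the full annotated span (a site in the first 50 bp carries both
the TSS and gene-body flags; multi-membership is intended). Per gene and
class, overlapping intervals are merged; everything is clipped to chromosome
bounds. Site annotation is point-in-interval via interval trees, with a
naive all-pairs oracle in the test suite. A site with no flag at all is
"nonregulatory".

## DMRs

DMSs are clustered left to right: repeatedly take the earliest maximal run
of consecutive sites whose first-to-last span (inclusive) fits in 2 kb and
which has ≥ 3 members, emit it, and continue after it. This is exactly the
greedy-left deduplication of an exhaustive scan of all 2 kb windows (the
test suite asserts equality with that oracle on random instances), and it
gives each DMS at most one DMR. A naive chain that always anchors at the
first unassigned site can miss clusters the window scan finds (sites at 0,
1999, 2050, 2100: the first two sites straddle a window boundary and strand
the remaining pair), which is why the maximal-run formulation is used. A DMR
is `constitutive_hyper`/`constitutive_hypo` when every member shifts the same
way in urban birds, else `mixed`.

## Over-representation

Feature enrichment uses 2×2 tables of the DMS set against the relaxed
genome-wide background (sites with ≥ 3 reads in ≥ 1 individual; the DMS set
is not excluded from the background). The reported odds ratio is the sample
cross-product (a/b)/(c/d) — the quantity that reproduces the published
values when recomputed from published summary counts — with the two-sided
Fisher exact p; tables with an empty margin are flagged degenerate and an
infinite or zero odds ratio is reported as such. Expressed genes are those
with raw count ≥ 10 in ≥ 25% of individuals (ceiling rule: 3 of 12). The
expressed-gene enrichment takes as property "linked via promoter, TSS or
gene body to ≥ 1 expressed gene"; in the DMR-restricted variant the focal
set is DMSs inside DMRs and the background keeps only sites that lie, with
two or more other sites, inside one 2 kb span (the DMR span convention).

GO over-representation is a one-sided hypergeometric upper tail per term,
after propagating gene annotations to all ancestors through is_a and part_of
edges (true-path rule; other relationship types are ignored, and evidence
codes are not filtered), with BH correction across tested terms (k ≥ 1).
The background defaults to genes with ≥ 1 term after propagation;
unannotated focal genes still count in the focal total. Semantic-similarity
reduction of the resulting term list is out of scope; full lists are
emitted.

## Methylation–expression model

For every DMS lying in the gene body, promoter or TSS of a gene with
quantified expression, one observation row per (DMS, gene, feature, sample)
is built — a DMS in several features of one gene contributes one row per
feature, and gene links are resolved per feature class so a site in gene A's
TSS and gene B's promoter never produces a "gene B TSS" row. Expression is
the size-factor-normalised log2(count + 1) (median-of-ratios size factors);
this stands in for a regularized-log transform — adequate here because the
model concerns slopes on the log scale, not shrinkage of near-zero counts,
and the transform used is recorded in the results object.

The model is `expression ~ methylation × feature` with a random intercept
per individual. When the REML estimate of the individual variance is
numerically zero (≤ 1% of the residual variance), the model is refit as a
fixed-effects linear model — the expected path under this study design, and
the two fits give identical slopes in that case (asserted in the tests).
Reported are per-feature marginal slopes with 95% t CIs, the interaction F
test against the no-interaction model, and Tukey-adjusted pairwise slope
differences via the studentized range with k = 3 groups and the residual df.
Rows are treated as exchangeable given the individual intercept; correlation
between rows of one gene is not modelled (the same simplification as the
source design, whose degrees of freedom imply independent per-sample rows).

## Synthetic data

The generator's defaults are the study conditions the analysis assumes:

* **Design**: 12 samples (6 urban, 6 forest), one 500 kb chromosome
  (`chr1`), ~6,300 CpG units.
* **Genome**: background drawn iid (GC ≈ 40%) with 75% of CG dinucleotides
  destroyed, giving CpG obs/exp ≈ 0.25–0.3; 8 planted islands of 800 bp with
  GC ≈ 66% and obs/exp ≈ 1.0, placed in evenly spaced slots with ≥ 2 kb
  clearance. CpG units are taken from actual CG dinucleotides.
* **Methylation baseline**: per-site Beta(0.5, 2.4), median ≈ 0.10 and
  right-skewed — the mostly-hypomethylated landscape RRBS reports.
* **Coverage**: per CpG unit and sample, each strand NB(mean 15,
  dispersion 8), so the destranded total is NB(30, 16) (CV ≈ 0.27, typical
  of per-site RRBS coverage); coverage is independent across sites and
  samples, with no positional autocorrelation.
* **Planted effects**: 60 true DMSs with an additive shift of 0.35 on the
  proportion scale; 75% hypermethylated in urban. Half sit in ten 3-site
  clusters within 2 kb (the true DMRs); 15 are singletons placed in the
  upstream portion of TSS windows of truth-expressed genes; the rest are
  free singletons. Planted baselines are drawn so the shift rarely clips
  ([0.05, 0.60] for hyper, [0.40, 0.95] for hypo); if clipping still
  compresses a realised shift to ≤ 25 points the site is dropped from the
  truth table. Clusters and free singletons avoid TSS windows so the
  TSS–expression coupling is exactly the configured slope.
* **Expression**: 60 genes in evenly spaced slots (≥ 800 bp apart so
  neighbouring TSS windows never overlap), 20% non-expressed (mean ≈ 1.4
  counts); expressed genes draw a baseline log2 mean from U(4, 10); genes
  carrying a planted TSS DMS draw from the upper half of that range so the
  coupling cannot push them below the expressed-gene rule, and each sample's
  log2 mean is shifted by −0.03 × (realised methylation % of that sample at
  the planted site). Counts are NB with dispersion 20.
* **Ontology**: a small is_a/part_of DAG (1 root, 4 branches, 16 leaves)
  with 1–3 random leaf annotations per gene — enough structure to exercise
  true-path propagation, not a model of real GO.

All outputs are byte-identical under a fixed seed. What the generator does
**not** emulate: read-level data and alignment, bisulphite conversion error,
positional autocorrelation of coverage and methylation, between-individual
(biological) overdispersion, CpG-density-dependent methylation (island CpGs
share the same baseline distribution as background CpGs), isoforms, and any
realistic GO topology. Passing tests therefore demonstrate that the
implementation is correct under its stated model, not that the pipeline's
error rates transfer to real RRBS data — in particular the absence of
overdispersion makes the site test exactly calibrated here, which real data
will not reproduce.

## Problem sizes in the tests and the acceptance script

The pipeline examples and acceptance measurements run at the generator
defaults above; the permutation test uses 100 iterations where the analysis
default is 1,000; slope-recovery coverage aggregates 20 simulated
replicates; end-to-end DMS recovery aggregates 5 replicates (expected counts:
sensitivity ≥ 0.8 chiefly limited by ~4% of planted units failing the 10×
everywhere rule, and a strict-25 boundary loss of ~2%; observed false
discoveries are essentially zero because the q < 0.01 and |diff| > 25
conjunction is conservative). These sizes are the package's chosen test
conditions; all thresholds are the analysis constants held in `RunConfig`.

## Known limitations

* No overdispersion (beta-binomial) option in the site test.
* The CGI detector's stretch rule can extend up to ~900 bp beyond a strong
  island's true edge; boundary precision was traded for recall.
* The rlog stand-in compresses low counts differently from the shrinkage
  transform it replaces; slopes on well-expressed genes are unaffected.
* GO results are only as meaningful as the annotation supplied; evidence
  codes and non-is_a/part_of relations are ignored.
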