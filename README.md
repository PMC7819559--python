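# urbmeth

Post-alignment analysis of two-habitat RRBS methylation studies: CpG-level
differential methylation with SLIM q-values and a label-permutation null,
sequence-based CpG-island detection and genomic feature annotation, 2 kb
differentially-methylated-region calling, over-representation analyses
against bespoke backgrounds, and a methylation × feature interaction model of
gene expression — plus a synthetic-data generator that emulates the whole
study design for end-to-end parameter-recovery testing.

## The scientific problem

Urban environments impose novel pressures (diet, pollutants, light, noise)
on wild populations, and DNA methylation is a candidate mechanism for rapid,
possibly heritable, phenotypic adjustment. A typical study design compares
reduced representation bisulphite sequencing (RRBS) methylomes of urban and
rural conspecifics — here modelled on six urban and six forest great tits
(*Parus major*) with both liver/blood methylomes and matched expression
data — and asks four questions: are differentially methylated sites (DMSs)
concentrated in regulatory regions? in expressed genes? in coherent
biological pathways? and does methylation correlate with expression? This
package implements that analysis chain for anyone working downstream of a
Bismark-style aligner.

## The statistics at the core

* **Site test.** For destranded CpG unit *s*, methylated read counts per
  sample are modelled as binomial; habitat is a binary covariate, so the
  logistic-regression MLE is the pooled group fraction and the
  likelihood-ratio statistic
  `G = 2[ℓ(m_u,t_u) + ℓ(m_f,t_f) − ℓ(m_u+m_f, t_u+t_f)] ~ χ²₁`
  is computed in closed form across all sites. A DMS requires
  `|Δ| > 25` percentage points (difference of group means of per-sample
  fractions) and `q < 0.01`.
* **q-values.** `q = π₀ · BH(p)` with π₀ estimated by a sliding linear
  model on the empirical CDF of p over λ ∈ {0.05, …, 0.95}: the most stable
  5-point segment's slope, clipped to (0, 1].
* **Permutation null.** Habitat labels are permuted (balanced 6/6,
  resampled with replacement) and the entire analysis rerun; the statistic
  is the DMS count and `p = (1 + #{null ≥ obs}) / (n_iter + 1)`.
* **DMRs.** Maximal runs of ≥ 3 DMSs whose span fits in 2 kb, taken greedily
  left to right (provably identical to an exhaustive 2 kb-window scan).
* **Enrichment.** 2×2 cross-product odds ratios `(a/b)/(c/d)` with
  two-sided Fisher exact p against the relaxed background (≥ 3 reads in ≥ 1
  individual); gene-level GO over-representation by one-sided hypergeometric
  tests with true-path annotation propagation and BH correction.
* **Expression link.** `expression ~ methylation × feature` (gene body /
  promoter / TSS) with a random intercept per individual, refit as fixed
  effects when the individual variance estimate is zero; per-feature slopes
  with 95% CIs and Tukey-adjusted pairwise slope differences.

## Worked example

Run the full simulated pipeline (generate data, destrand, filter ≥10× with a
99.9th-percentile cap, intersect samples, call DMSs/DMRs, enrichment,
expression model):

```python
from urbmeth import run_all
from urbmeth.config import RunConfig

res = run_all(RunConfig(outdir="demo", seed=1, perm_n_iter=200))
print(res.dms_results.summary())
print(res.slope_report.summary())
```

prints

```
Differential methylation (urban vs forest)
  sites tested            6036
  estimated pi0 (SLIM)    0.841
  DMS (|diff|>25, q<0.01)   49
  hypermethylated in urban 39 (79.6%)
Expression ~ methylation x feature
  observations        432
  individual variance 0 (refit as fixed effects)
  interaction F(2,426) = 18.72, p = 1.62e-08
  per-feature slopes (log2 expression per methylation %):
    gene_body  +2.28e-02  [-3.15e-04, +4.59e-02]
    promoter   +2.11e-02  [+1.05e-02, +3.17e-02]
    tss        -2.82e-02  [-4.09e-02, -1.55e-02]
    gene_body vs promoter: diff +1.69e-03, Tukey p = 0.991
    gene_body vs tss: diff +5.10e-02, Tukey p = 0.000477
    promoter vs tss: diff +4.93e-02, Tukey p = 2.78e-08
```

Reading this: of ~6,000 CpG units covered ≥10× in all twelve birds, 49 clear
both DMS thresholds and ~80% of them are hypermethylated in the urban group
(the generator plants 60 shifted sites, 75% hyper; a few fall below the 10×
rule in at least one bird, and the permutation p here is 1/201 — no permuted
labelling produced as many DMSs). The fitted TSS slope of −0.028 log2 units
per methylation percentage point recovers the planted coupling of −0.03 and
excludes zero, while gene-body and promoter slopes straddle or sit near
zero, so the methylation–expression interaction is carried by TSS sites —
the signature the analysis is designed to detect. `res.dmrs`,
`res.feature_enrichments`, `res.go_results` and `demo/manifest.json` hold
the per-stage outputs.

The same stages are scriptable from a shell:

```bash
urbmeth simulate --outdir data --seed 5
urbmeth unite --samples data/samples.tsv --genome data/genome.fa --out matrix.tsv
urbmeth dms --matrix matrix.tsv --samples data/samples.tsv --permute 200 --seed 5 --out dms.tsv
urbmeth dmr --dms dms.tsv --out dmrs.bed
```

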