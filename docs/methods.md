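# Methods

This note documents the statistical models implemented in `admixomics`,
the defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical conventions used
throughout.

## Supervised admixture estimation

For a sample with alt-allele dosages `g_m ∈ {0,1,2}` at M ancestry-informative
markers (AIMs) and fixed reference allele frequencies `f_km` for K
populations (AFR, AMR, EAS, EUR, SAS in 1000 Genomes super-population
order), the admixture vector `q` on the K-simplex maximises the binomial
log-likelihood

    ℓ(q) = Σ_m [ g_m ln a_m + (2 − g_m) ln(1 − a_m) ],   a_m = Σ_k q_k f_km.

`ℓ` is concave in `q` (it is a sum of concave functions of the linear map
`a(q)`), so the EM fixed-point update

    q_k ← (1/2M′) Σ_m [ g_m q_k f_km / a_m + (2 − g_m) q_k (1 − f_km) / (1 − a_m) ]

from the uniform start converges to the global maximiser; no restarts are
used, and the test suite verifies agreement with a dense grid search at
K=2. `M′` counts the markers with a non-missing dosage: missing genotypes
are dropped per sample, not imputed. Samples with no observed marker are
flagged and skipped while the rest proceed.

Numerical conventions: reference frequencies are clamped to
`[1e-6, 1 − 1e-6]` so the log-likelihood stays finite at fixed alleles;
convergence is declared when the log-likelihood improvement falls below
`tol` (default 1e-8) — the criterion is on the objective, not on `q`,
because near-flat directions of the likelihood move `q` without moving
`ℓ`. The default iteration cap is 1000; at the study scale (M=654, K=5,
moderately differentiated populations) full convergence to `Δℓ < 1e-8`
typically needs ~1500–2500 iterations, so analyses that need fully
converged estimates should raise `max_iter` (the recovery analyses in
this repository use 20000). The log-likelihood is non-decreasing at every
iteration, which the suite asserts along the trajectory.

Statistical precision: with M=654 markers at Balding–Nichols
differentiation F=0.15 the maximum-likelihood estimate itself carries a
mean per-component absolute error of roughly 0.03–0.05 depending on how
admixed the truth is (interior `q` vectors are hardest; near-vertex
vectors are easiest). This is a property of the design, not the
optimiser: the EM solution matches direct simplex optimisation of the
same likelihood to numerical precision. Real AIM panels are selected for
extreme between-population frequency differentials and are therefore more
informative per marker than Balding–Nichols draws at a continental-scale
F.

### Group assignment

Samples are classified by strict thresholds on `q`: African-ancestry (AA)
requires AFR > 0.20, AMR < 0.10 and AFR + EUR > 0.70; European-ancestry
(EA) requires EUR > 0.80 and AMR < 0.10; everything else — including
exact boundary values — is excluded. The two rules are mutually exclusive
(AFR > 0.20 forces EUR < 0.80). Tumour/normal concordance is summarised
as a per-population Pearson r; a constant component is reported as
undefined (NaN, flagged) rather than 1.

## Synthetic cohort generator

No patient-level data from the motivating cohort is available, so all
pipeline stages are exercised on synthetic cohorts that reproduce the
cohort's *statistical structure*:

* **Reference panel.** Balding–Nichols: ancestral frequency
  `f ~ U(0.05, 0.95)`, population frequency
  `f_k ~ Beta(f(1−F_k)/F_k, (1−f)(1−F_k)/F_k)`, so `F_k` is an FST
  analogue (a Hudson-style ratio-of-averages estimator over the generated
  panel recovers `F` — asserted in the tests). Default F=0.15 per
  population, a typical continental-scale differentiation. Chosen because
  it is the standard single-parameter frequency model; the trade-off
  noted above (less informative than a real AIM panel) is accepted.
* **Genotypes.** `g ~ Binomial(2, Σ_k q_k f_km)` — the exact generative
  counterpart of the estimation likelihood. Truth `q` vectors used in
  recovery analyses are drawn Dirichlet with concentration 0.3: cohort
  ancestry vectors are dominated by one component, and a flat Dirichlet
  would overweight maximally admixed individuals that real cohorts rarely
  contain.
* **Clinical records.** Stage, subtype (HR+/HER2−, TNBC, Other) and
  grade are independent categorical draws with the published cohort
  composition as defaults (623 AA / 2810 EA patients; e.g. AA stage IV
  519/623 = 0.8331, EA TNBC 400/2810 = 0.1423); age is normal with the
  published mean/SD per group, truncated at 18.
* **Mutations.** Per-gene carrier indicators are Bernoulli with
  (group, subtype)-specific prevalences taken from the published
  oncoplots (e.g. PIK3CA in HR+/HER2−: 0.34 AA vs 0.42 EA; KMT2C in
  TNBC: 0.23 vs 0.12; TP53 whole-cohort 0.59 vs 0.49 standing in for the
  unprinted "Other" stratum). Genes are independent — no co-occurrence
  or mutual-exclusivity structure is modelled.
* **Counts.** `log2 μ_gj = baseline_g + b_g·[batch=v2] + β_g·[AA] +
  log2(libsize_j/1e6)`, counts negative-binomial with variance
  `μ + φμ²` and lognormal dispersion `φ_g` (meanlog ln 0.1, sdlog 0.5 —
  typical bulk RNA-seq dispersions). Assay batch v1/v2 is Bernoulli(0.5)
  per sample, matching the reported near-50/50 assay split; batch shifts
  `b_g ~ N(0, 0.25²)` are "minor" on the log2 scale. A `de_fraction`
  (default 5%) of genes carries a planted ancestry effect `β_g = ±2`
  (sign random), and the true-effect registry is returned so recovery can
  be scored without re-deriving ground truth.

What the generator does **not** emulate: linkage disequilibrium between
AIMs, tumour purity/CNV distortion of dosages, gene–gene expression
correlation, mutation co-occurrence, subtype-dependent expression
programs, or read-level artefacts. Passing tests therefore demonstrate
that the estimators are correct and calibrated under the assumed
generative structure — not that the pipeline is robust to every artefact
of real tumour sequencing data.

## Differential-expression meta-analysis

The cohort's counts come from two versions of one exome-capture RNA-seq
assay; differential expression is computed within each batch and then
combined, rather than modelling batch as a covariate.

* **Per-batch statistic.** Moderated two-sample t on
  `log2 CPM = log2((count + 0.5)/(libsize + 1) · 1e6)`. The per-gene
  pooled variance is shrunk toward an empirical-Bayes prior,
  `s̃² = (d0·s0² + df·s²)/(d0 + df)`, and the t reference gains d0 df.
  The prior is fitted by method of moments on `z = ln s²`
  (`var(z) = trigamma(df/2) + trigamma(d0/2)`, inverted by Newton on the
  trigamma function, with the digamma bias correction for `s0²`). When
  the observed spread of `z` is below `trigamma(df/2)` the prior df is
  infinite (z-test against `s0²`); when the variances have literally no
  spread the shrinkage target is their common value. The original
  analysis used a negative-binomial DE engine; the moderated t on logCPM
  is used here because the package's claims about DE are *property-based*
  (type-I calibration, planted-effect recovery, direction handling), and
  those properties are engine-robust — the suite verifies type-I error
  within its binomial band on NB-generated null counts. TMM-style
  normalisation factors are not applied; library-size CPM suffices for
  the calibration and recovery properties asserted.
* **wFisher p-value combination.** Batch weights `w_i = n_i/Σn`. Each
  two-sided `p_i` is folded one-sided toward a *fixed* orientation
  (positive = higher in AA): `p_i/2` when the batch logFC is positive,
  `1 − p_i/2` otherwise. The folded values are mapped through upper
  Gamma(K·w_i, scale 2) quantiles and summed; the total is referred to
  Gamma(K, scale 2), and the two-sided meta-p is `2·min(meta, 1−meta)`.
  Under the null (uniform p, random signs) every ingredient is exactly
  uniform, so the meta-p is exactly uniform — the suite verifies this
  with a 50,000-rep KS test. Folding toward the *data-chosen* winning
  direction instead would always halve the dominant batch's p and is
  measurably anticonservative; that variant was rejected for exactly
  this reason. At equal weights every gamma shape is 1 and the statistic
  reduces to classical Fisher (−2Σln p′ against χ² with 2K df) to
  machine precision; a single batch returns its own p unchanged.
* **Effect combination and filtering.** Meta-logFC is the sample-size
  weighted mean of per-batch logFCs (EA as the reference group). A gene
  is flagged significant only when the per-batch logFC signs agree
  *and* the meta-p passes the Bonferroni cutoff `alpha_family / G`
  (0.01/10,000 = 1e-06 at the study's family size; the family is always
  the number of genes actually tested, recorded in the run metadata).
  Direction filtering is applied before the significance flag; the full
  table is returned regardless.

Monotonicity caveat: the two-sided meta-p is monotone non-decreasing in
each input p only while the combined evidence stays on one side —
weakening an opposing batch strengthens the evidence for the other
direction. The property test asserts monotonicity in the aligned regime.

## ssGSEA

Per sample, genes are ranked by expression (average ranks for ties) and
walked in descending order; a set's score is the accumulated gap between
the rank-power-weighted in-set ECDF (`r^α`, α = 0.25) and the unweighted
out-of-set ECDF. Only within-sample ranks enter, so scores are invariant
to any strictly increasing per-sample transform (property-tested). With
`normalize=True` the score matrix is divided by its global (max − min) —
one scalar, ordering preserved. α = 0.25 and the global normalisation
follow the single-sample convention of the GSVA-family implementations;
an independent implementation (gseapy) agrees with the scores at
r > 0.9999 on random fixtures. A set covering the whole gene universe
has an undefined out-of-set ECDF and is rejected; sets with no overlap
with the matrix are dropped with a warning.

Per-set group comparison reuses the moderated-t machinery across sets
(EA reference) with the Bonferroni cutoff `alpha_family / n_sets`
(0.01/239 = 4.18e-05 for the hallmark-plus-oncogenic-scale family,
printing as 4.2e-05 at two significant figures). The family size is
always taken from the sets actually scored in the run.

## Contingency statistics

2×2 comparisons use the Pearson chi-squared with Yates continuity
correction (each |O−E| reduced by 0.5, floored at 0). With the
correction on, the test reproduces all three published cohort-level
P-values recomputable from printed counts (TNBC 9.56e-08, HR+/HER2−
5.14e-06, stage IV 0.53) to two significant figures — this fixes the
correction convention for the whole package. r×c tables use the
uncorrected statistic, the usual convention beyond 2×2. Zero-margin
tables return p = 1 flagged degenerate (2×2) or drop the degenerate
rows/columns with a warning (r×c).

The published tumour-grade P-value (5.59e-07) is *not* reproduced by
either high-vs-low excluding unknown (3.4e-08) or the full 2×3 table
(1.0e-09) from the printed counts; the grouping actually tested is
unclear, so the cohort table reports both variants and pins neither.

Gene-wise multiplicity uses Benjamini–Hochberg (the source states only
"adjusted"); BH is the standard choice for gene-screening FDR control
and is recorded in the output metadata. Family-wise (Bonferroni)
correction is used where the source's printed cutoffs imply it (DE and
enrichment families above).

## Known limitations

* The per-batch DE engine and the enrichment comparison are moderated-t
  based, not negative-binomial/limma re-implementations; gene-by-gene
  numerical agreement with the original analysis is out of scope (the
  original cohort data are proprietary), and all claims are calibration
  and recovery properties.
* Admixture estimation consumes hard dosages; genotype likelihoods,
  tumour purity and CNV effects on allele counts are not modelled.
* The synthetic cohort's independence assumptions (genes, markers,
  patients) make multiplicity behaviour cleaner than in real data, where
  correlation inflates the variance of discovery counts.
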