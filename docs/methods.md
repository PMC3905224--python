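# Methods

`gwaspath` implements the inference chain used in cross-cohort GWAS pathway
studies of quantitative traits: per-cohort single-SNP association, fixed-
effect meta-analysis, an LD-aware gene-based test, competitive gene-set
enrichment with an empirical validation step, and Stouffer combination of
enrichment evidence across cohorts. This note records the statistical models,
the defaults and why they were chosen, what the synthetic-cohort generator
does and does not emulate, and the numerical decisions made where the design
was genuinely open.

## Phenotype construction

Cognitive (or any multi-test) batteries are reduced to a single score as the
first unrotated principal component of the test **correlation** matrix,
regression-scored (loading-weighted standardized tests scaled by the inverse
eigenvalue) and standardized. The correlation rather than covariance matrix
is used because battery tests are on arbitrary scales; for standardized
inputs the two coincide. The component is oriented so the mean test loading
is positive, which keeps the score's sign stable across resamples of the
same battery. Age and sex are removed by ordinary least squares after factor
extraction, and the standardized residuals carry forward; residualisation
before extraction is algebraically available by scoring residualised tests,
but residualise-after is the default path. Composite phenotypes are the
re-standardized per-sample mean of two standardized scores. Missing test
scores are handled by listwise deletion; model-based factor-score imputation
is out of scope.

## Quality control and association

Per-SNP QC applies, in order: call rate (default > 0.98), minor allele
frequency (> 0.01 for genotyped SNPs, > 0.005 for imputed dosages), an
imputation-quality floor (> 0.3, only when a quality vector is supplied),
and an exact Hardy-Weinberg test (P > 0.001). HWE uses the exact conditional
distribution of the heterozygote count given the allele counts, evaluated on
hard calls (rounded dosages) from the genotyped subset; the exact rather
than chi-square form is used because it is well defined at low counts and
the thresholds' semantics are unchanged. The first failing check is the
recorded removal reason.

Association is additive-model OLS of the phenotype on dosage plus
covariates, computed by the Frisch–Waugh decomposition (phenotype and all
dosage columns residualised once on the covariate block), which is exact OLS
and vectorises over SNPs. Missing dosages are mean-imputed per SNP.
Monomorphic SNPs are emitted with beta 0, p 1 and a flag rather than
dropped, so downstream joins stay aligned; the meta-analysis excludes them.
P-values are clipped at the smallest positive double to guard underflow at
extreme signals.

Cohorts are combined by classical inverse-variance weighting:
w_i = 1/se_i², pooled beta = Σwβ/Σw, se = (Σw)^(-1/2), two-sided normal P.
Effect alleles are harmonised to the first cohort's orientation; a cohort
reporting the swapped allele pair has its beta and frequency flipped, and
irreconcilable pairs are dropped with a warning. No heterogeneity or
genomic-control statistics are computed.

## Gene-based test

SNPs are assigned to genes within ±50 kb of the gene body, inclusive at
both ends; a SNP inside several windows counts for each gene. The window is
anchored at the annotated gene start/end because UTR coordinates are not
part of the annotation model. The gene statistic is S = Σz², where z are
the (meta-analysed) SNP Z-scores in the gene's window. Its null accounts
for SNP count and LD by Monte Carlo: draws u ~ MVN(0, R) with R the Pearson
dosage-correlation matrix of the gene's SNPs, estimated from the analysis
cohort's own genotypes (no external reference panel) and repaired to
positive semi-definite by eigenvalue clipping at 1e-6 with unit-diagonal
rescaling. The empirical P is (1 + #{Σu² ≥ S}) / (B + 1); the add-one
correction keeps P strictly positive and the simulation count is recorded
per gene. B follows an adaptive ladder (10³, 10⁴, 10⁵ by default,
configurable cap) escalating while fewer than 100 null exceedances have
been seen, so small P-values rest on adequate tail mass. Single-SNP genes
take the SNP's own two-sided P, the exact 1-df case of the statistic.
Per-gene seeds are derived from (master seed, gene id) so partial or
parallel runs reproduce. Genes are then ranked by descending −log10 P with
lexicographic tie-breaks.

## Competitive enrichment

Walking the ranked gene list, a set member at rank j adds
r_j^w / Σ_hits r^w and a non-member subtracts 1/(N − N_H), where r is the
−log10 gene P and w ∈ {0, 1}. The enrichment score is the maximum value the
walk attains; the walk ends at exactly zero by construction, so ES ∈ [0, 1]
and only top-of-list enrichment is scored (depletion is not tested). The
weighted form (w = 1) is the discovery default; w = 0 gives the
unit-weighted statistic used for replication analyses. If every hit weight
is zero the hit increments fall back to uniform, which is the w = 0 case.

The null is competitive: uniformly drawn same-size gene subsets of the
ranking (equivalent to permuting gene labels), 15 000 draws by default,
with P = (1 + #{ES* ≥ ES}) / (n_perm + 1). Gene-label rather than phenotype
permutation is used because phenotype permutation would require re-running
the entire GWAS chain per draw. FDR follows the GSEA-style ratio estimator:
each set's ES and null sample are normalised by the mean positive null ES
of its size (NES); q = (pooled-null exceedance fraction)/(observed
exceedance fraction) at the set's NES, clipped to [0, 1] and monotonised so
a higher NES never receives a larger q. With a single set the estimator
collapses to the permutation P.

Sets called at P ≤ 0.05 and/or q < 0.25 can be validated empirically: 1000
random size-matched sets are each analysed with a reduced budget (2000
permutations per set by default, chosen to keep the nested Monte Carlo at
desk scale; a full-budget flag exists), family-wise q-values are computed
across them, and the observed set validates when its P and q beat at least
95% of the random sets. Leave-one-out sensitivity removes the set member
with the largest ranking weight and re-tests the remainder. Candidate genes
absent from the ranking (no SNPs after QC) are dropped and the reported set
size is the intersection size.

## Evidence combination

Enrichment P-values are one-sided by construction, so cohorts combine with
Stouffer's weighted Z-transform: Z_i = Φ⁻¹(1 − p_i), weights √n_i,
Z = Σw_iZ_i / √(Σw_i²), combined p = 1 − Φ(Z). Square-root-sample-size
weights are the standard weighted-Z choice; the result is invariant to
rescaling all weights. P-values are clipped to [1e-300, 1 − 1e-16] before
the quantile transform, with a warning. The discovery cohort's P is
Bonferroni-corrected (min(1, m·p)) for the number of set-by-phenotype
hypotheses before combination.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes
without claiming demographic realism. Genes are laid on one chromosome with
a 150 kb inter-gene gap (so ±50 kb windows are disjoint; an overlap mode
places two genes within 50 kb to exercise multi-assignment), each carrying
3–8 SNPs at 2 kb spacing with target MAF uniform on [0.05, 0.5]. Haplotypes
are generated per gene by Gaussian-copula thresholding: a latent AR(1)
Gaussian vector with adjacent-SNP correlation ρ (default 0.7) dichotomised
at the MAF-matching quantile; an individual is the sum of two independent
haplotypes. This yields geometrically decaying LD with marker distance and
realised frequencies tight around their targets, reproducibly and with one
parameter, which is why it was preferred to coalescent simulation. Cohorts
are independent draws from the same process, with per-cohort generator
streams derived from (master seed, cohort index) so adding a cohort never
perturbs an earlier one.

Phenotypes follow a latent-factor model. A causal gene set (50 of 500 genes
by default, seeded uniform draw) carries per-SNP effects drawn centred at
zero; the standardized weighted dosage sum is scaled to variance h²_set
(default 0.2), a background score over all remaining genes to
h²_background (default 0.05, a diffuse polygenic floor), and a Gaussian
residual makes latent g unit-variance. Each of 4 battery tests is
loading·g + √(1 − loading²)·noise (loadings 0.7) plus additive age and sex
nuisance effects (age discrete-uniform 55–75 years, slope −0.03 per year;
sex Bernoulli(0.5), shift 0.1), so the residualisation step has real work
to do. A size-matched decoy set drawn independently of the causal set
provides a negative control whose overlap with the causal set follows the
hypergeometric law. Effect sizes are chosen for test power at n = 2000,
not to mimic any particular cohort: no published effect-size scale exists
for this design. The generator does not emulate relatedness or family
structure, X-linked variation, population stratification, genotyping
batch effects, or imputation uncertainty — so passing calibration and
power checks here demonstrates the statistical machinery is correct under
the stated model, not that real-cohort confounding is handled.

## Problem sizes and numerical choices

Calibration and power studies run the full chain per replicate at n = 2000
samples, 500 genes (~2 750 SNPs), with reduced Monte-Carlo budgets (gene
test ladder 10³→10⁴, 2 000 enrichment permutations): 200 null replicates
check that the causal set's enrichment P is uniform and the type-I error at
0.05 sits inside its binomial confidence band; 20 signal replicates check
the median causal-set P falls below 0.05 while the decoy stays nominal.
These sizes were chosen so the studies complete on a single CPU at desk
scale while leaving the binomial error bands tight enough to be
informative.

Other numerical choices: LD repair threshold 1e-6 with unit-diagonal
rescaling; Cholesky factorisation with an eigen fallback for rank-deficient
LD (perfect-LD duplicates are legitimate inputs); ranking ties broken
lexicographically for determinism; zero-variance tests, degenerate
residuals, empty causal sets, disjoint or saturated gene sets, and
boundary P-values of 0 or 1 all raise errors naming the offending object.
All randomness flows from a single master seed through derived, recorded
per-stage streams (never global state); string contexts hash through a
fixed FNV-1a so streams are stable across processes.

## Known limitations

The gene-based statistic is the all-SNP sum form only (no top-SNP
variants). Enrichment scores only top-of-list enrichment; depletion and
leading-edge reporting are not implemented. The FDR estimator is the
GSEA-style ratio, which is itself a Monte-Carlo quantity and can be 0 when
the observed NES exceeds every pooled null value. MDS/stratification
covariates are accepted as input columns but never computed. Family-based
designs are not modelled; all cohorts are treated as unrelated samples.
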