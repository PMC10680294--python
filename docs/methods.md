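# Methods

This note documents the statistical models implemented in `cellcis`,
the choices made where the design was genuinely open, and what the
synthetic-data studies do and do not demonstrate.

## Study conditions emulated

The package targets the scale of a single-cell multiomics cohort of
about 20 donors: pseudobulk phenotypes per (sample, cell type), common
variants (MAF ≥ 0.1, ≥ 4 minor-allele carriers, missingness ≤ 20%), a
±250 kb cis window around the gene TSS (caQTL candidates reside inside
their peak), and candidate variants restricted to open chromatin of the
tested cell type. Defaults throughout (20 samples, MAF ∈ [0.1, 0.5],
depth ≈ 50 reads per site per assay, FDR 0.10) mirror that setting.

## Association model and multiple testing

The cis scan is ordinary least squares of the transformed phenotype on
dosage, covariates and an intercept; p-values come from the t statistic
with n − k − 2 residual df. It is computed by Frisch–Waugh
residualization against the covariate block, which is algebraically
identical to the full regression and vectorizes over variants. Missing
dosages are mean-imputed per variant; zero-variance dosages are dropped.
Exact fits report the smallest positive double rather than 0 so that
p ∈ (0, 1] holds everywhere.

Phenotypes are quantile-normalized across samples and/or rank-based
inverse-normal transformed per feature. The INT uses the Blom offset,
value = Φ⁻¹((rank − 3/8)/(n + 1/4)), with average ranks for ties; the
offset is configurable (the transform is often cited without one).

Hidden-factor covariates default to the top three phenotype principal
components plus genotype PC1 — four covariates, standing in for
factor-analysis confounder estimates and an ancestry axis. A caveat
discovered while validating recovery: with only a few hundred features
and very strong planted effects, phenotype PCs align with individual
planted dosage vectors and absorb them. The recovery studies therefore
run without hidden-factor covariates (they simulate no confounding);
covariate behavior is validated separately with an explicitly planted
confounder, where including the confounder restores the planted slope.

*M*<sub>eff</sub> is the smallest k whose top-k eigenvalues of the
variant correlation matrix (pairwise-complete, zero-variance variants
removed) reach 99% of the trace; sets larger than 200 variants are split
into consecutive windows of ≤ 200 and the window values summed. The
feature-level p is min(1, p_min · M_eff); study-level control is BH at
FDR 0.10 per cell type. At very high LD and with candidates spanning
many weakly-coupled blocks, the 99%-variance rule undercounts effective
tests and the feature-level p is mildly liberal; calibration was
verified in the regime the package simulates (≈ 10–20 candidates per
feature, one LD block).

The permutation scheme reruns the identical scan once with sample
labels permuted (seeded) and picks the largest observed feature-level p
with (1 + #{null ≤ t}) / max(1, #{true ≤ t}) ≤ FDR. The +1 numerator is
the standard conservative permutation-FDR estimator; without it, a
handful of pure-null features are called whenever the extreme order
statistics happen to fall on the observed side. A consequence worth
knowing: at FDR 0.10 no threshold can admit fewer than 10 features, so
very small studies either call a block of features or none.

LD clumping is the greedy plink procedure (p1 = p2 = 0.05, r² ≥ 0.5,
250 kb); ties on p are broken by distance to the anchor (TSS for genes,
summit for peaks), then by the smaller coordinate.

## Allele-specific signals

For ASCA, each qualifying heterozygote (≥ 10 reads in WGS and in ATAC)
contributes a one-sided Fisher exact p for the table
[[ATAC alt, ATAC ref], [WGS alt, WGS ref]] — computed as the exact
hypergeometric tail, vectorized over tables. Per variant and direction,
p-values are combined by Stouffer's method weighted by each sample's
total reads (WGS + ATAC, the sum convention), Z = Σwᵢ Zᵢ/√Σwᵢ²; the more
significant direction is kept, BH runs per cell type, and variants with
fewer than 3 qualifying heterozygotes are excluded. Input p-values are
clipped to [1e−300, 1 − 1e−16] to keep Z finite. The effect size — not
fixed by convention — is the read-weighted mean over heterozygotes of
(ATAC alt fraction − WGS alt fraction): bounded in [−1, 1] and
sign-aligned with the kept direction.

The ASE estimator is deliberately simpler than haplotype-population
tools: per variant–gene pair with ≥ 4 heterozygotes, the effect is
mean log2((alt hap + 1)/(ref hap + 1))/2 (halved to compare with a
per-allele slope) and the p-value a two-sided Wilcoxon signed-rank of
the per-het log-ratios; pairs with all-zero ratios report p = 1.

## Linking, master/dependent peaks

Links are Pearson correlations across matched pseudobulk aggregate
columns (sample × cell type), p from the t distribution with n − 2 df,
BH per channel. Defaults: co-accessibility r ≥ 0.2 and FDR < 0.05;
peak-to-gene r ≥ 0.45 and FDR < 1e−4 (the peak-to-gene cutoffs follow
the convention of the standard single-cell toolkit and are exposed as
parameters). A binarize flag thresholds accessibility at > 0 before
correlating. A gene's LCREs are the union of non-promoter peaks linked
directly to it and non-promoter peaks co-accessible with any of its
promoter peaks (promoter = TSS ± 1 kb, ≥ 1 bp overlap; minus-strand TSS
is the interval end).

The dependent-peak scan regresses every other peak within ±250 kb of a
called caQTL variant on its dosage with the same linear model and keeps
nominal p < 0.005 (no further correction, by design). A candidate
dependent that is itself a master peak whose resident caQTL has
r² > 0.5 with the tested variant is removed; the filter is a pure
subset operation and idempotent.

## Motif perturbation

PWMs carry per-position base probabilities; scoring is log2 odds versus
the background (uniform by default) with a 1e−3 pseudocount, on both
strands, min–max normalized to [0, 1]. The match threshold t(p) solves
P(score ≥ t) ≤ p under the background by discrete convolution of
per-position score distributions with bin width 1e−3 of the score
range; per-position scores are floored onto the grid and the threshold
shifted up one bin per position, so the tail guarantee holds exactly
and t exceeds the unrounded minimal threshold by at most L/1000 of the
score range. Note that with a uniform background no 6-mer can pass at
p = 1e−4 (the single best sequence already has probability
0.25⁶ ≈ 2.4e−4); meaningful matching at that stringency needs motifs of
length ≥ 7. Variant scoring restricts both alleles to offsets
overlapping the variant base; "strong" means an allele-score difference
≥ 0.4 on the normalized scale — an adopted convention, exposed as a
parameter, meaningful when the perturbed position carries a large share
of the motif's information. The TF-context test is a one-sided
Wilcoxon rank-sum (normal approximation without continuity correction,
so identical samples give exactly p = 0.5) over TFs with CPM ≥ 50 in
either cell type; fewer than 3 eligible TFs report a missing p.

## MPRA

Barcode × replicate units with DNA < 10 are dropped; the unit log-ratio
is log2((RNA + 0.5)/(DNA + 0.5)); an element's activity is its unit
mean minus the basal-promoter unit mean; significance is a Welch t-test
of element units against basal units with BH across elements. Units are
treated as exchangeable (a replicate-mean alternative is available).
Enhancer: log2FC ≥ 1 and q < 0.05; silencer: log2FC ≤ −1 and q < 0.05;
anything else — including large fold changes with q ≥ 0.05 — is
inactive. Annotation enrichment is a one-sided Fisher exact test of
class versus background membership.

## GWAS integration

Annotation categories follow a fixed priority: 4 exonic/UTR,
3 promoter, 2 LCRE, 1 OCR, 0 otherwise. Evidence per variant is the
Wakefield log-ABF, ½log(1−r) + z²r/2 with r = W²/(se² + W²) and
W = 0.15 (quantitative traits) or 0.2 (binary). Each LD block is
assumed to hold exactly one causal variant; enrichment coefficients
α_c (α₀ = 0) for the prior π_j ∝ exp(α_{c(j)}) are estimated across
blocks by EM, with the M-step's concave multinomial-logistic objective
solved exactly (L-BFGS with analytic gradient), which guarantees the
marginal likelihood is non-decreasing. PIPs are π_j·ABF_j normalized in
log space; the 95% credible set is the smallest PIP-descending prefix
reaching 0.95. Colocalization follows the standard ABF enumeration of
H0–H4 with priors p1 = p2 = 1e−4, p12 = 1e−5, computed in log space.

The summary-statistic generator draws z_j = r_{j,causal}·z_causal +
N(0, 1) with independent noise per variant. Under strong LD this
deviates from the correlated-noise joint model the single-causal
posterior assumes, so a neighbour occasionally out-scores the causal
variant and enrichment estimates attenuate toward zero. The recovery
and coverage studies therefore use mild LD (within-block copy
probability 0.3), where the model is well specified; the attenuation
under strong LD is a known limitation of single-causal fine-mapping,
not of the estimator's implementation.

## Synthetic data: what it does and does not show

LD is a block-mosaic copy-with-mutation scheme: one allele frequency
per block, each haplotype copying its left neighbour with probability
`ld_decay` — exact marginals, pairwise r ≈ ld_decay^distance,
independent blocks. Counts are Poisson (MPRA) and binomial (allelic),
with an optional negative-binomial dispersion parameter that defaults
to 0; sequencing depths for allelic counts are fixed at their per-assay
means so the planted binomial fraction is the only source of imbalance.
Haplotype phase is emitted exactly. All randomness flows from one seed
through named substreams, so planting an effect in one cell type leaves
every other cell type's draws byte-identical.

Passing the recovery studies shows the estimators are correctly
implemented and calibrated under this generative model. It does not
demonstrate robustness to what the generator omits: overdispersed
counts, mapping bias at heterozygous sites, phasing error, population
structure, cell-type misassignment, or confounding beyond the planted
cases. The paper-scale analyses these methods come from handle several
of those with tools (read-level bias correction, statistical phasing,
factor analysis) that are intentionally out of scope here.

## Problem sizes

The test-suite studies use 20-donor cohorts with 200–400 variants and
20–200 features per run, 10,000 variants for allelic calibration, and
50–200 LD blocks of 20–50 variants for the GWAS studies; replicate
counts (10–100 seeds per study, 25–50 in the acceptance script) were
chosen so each headline proportion carries a standard error of a few
percent.
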