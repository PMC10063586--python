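# Methods

This note records the models implemented in `cellrisk`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data studies
do and do not establish.

## Synthetic genome and GWAS model

Variants live on a single chromosome in disjoint LD blocks of fixed size
(default 10). Within a block the unsigned correlation follows either an
AR(1) profile |r|(i,j) = ρ^|i−j| (default ρ = 0.9) or an exchangeable
profile; the sign of r(i,j) is s_i·s_j for a per-variant Rademacher vector,
which keeps every block matrix positive semi-definite — arbitrary
independent per-pair signs would not. MAF is uniform on [0.05, 0.5];
positions are strictly increasing with geometric spacing (mean 2 kb).
Cholesky factors are cached per block profile; a ridge of 1e−6 is added to
the diagonal only if factorization fails.

GWAS Z-scores are drawn per block from a multivariate normal with
correlation equal to the signed LD and mean equal to the LD-propagated
non-centrality mean_i = Σ_j r_ij β_j √(2·MAF_j(1−MAF_j)·n_eff). Two-sided
p-values come from the normal tail, floored at the smallest positive float.
This is the standard large-sample model for summary statistics under joint
genotype normality; it ignores case-control imbalance corrections and
imputation noise (INFO is fixed at 1 in simulation).

Gene models are isoform-resolved and anchored in the central third of one
LD block each, with exons kept narrow around an anchor variant. This
placement is deliberate: 2-kb promoter windows then stay inside their
block's physical span, so planted causal signal cannot leak into a
neighboring block's gene and recovery tests measure the mapping logic, not
the placement luck.

Genotypes use a Gaussian copula: two haplotype latents per individual with
the block correlation, thresholded at the (1−MAF) normal quantile. Marginal
dosages are exactly Binomial(2, MAF); the realized genotype correlation is
a known attenuation of the latent r (checked in tests by sign and
magnitude), which is acceptable because the pipeline consumes r² only
through thresholding. Disease status follows a liability-threshold model:
liability = Σ β_std·z(dosage) + N(0, 1−h²), case iff liability exceeds
Φ⁻¹(1−K). Causal variants are planted at most one per block so the genetic
variance is exactly Σ β_std² = h². Case-control sampling rejects from the
population and raises once a draw budget (default 5·10⁶) is exhausted, as
happens at very small K.

Quantitative phenotypes are β·(standardized genetic score) + 0.1·(z-age +
z-duration + sex) + noise, scaled to unit total variance.

What the generator does *not* emulate: haplotype coalescence, allele
frequency/LD coupling, sex chromosomes, imputation error, population
stratification correlated with genotype (PCs are pure noise covariates),
and cross-block LD. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Cell-type-specific peaks

Peak identity across cell types is defined by membership in a merged
consensus unit (≥ 1 bp overlap joins; bookended intervals stay separate).
A unit is specific iff its membership count ≤ max_sharing_fraction ×
n_cell_types, inclusive at the boundary (3 of 6 qualifies at the default
0.5). The alternative reading — "present in exactly one cell type" — is
available by setting max_sharing_fraction < 1/n_cell_types.

## Enrichment

Greedy pruning keeps variants in ascending p order (ties broken by
position), discarding any variant with r² > 0.01 within 500 kb of an
already-kept one; clumping for scores uses the same contract at r² = 0.1
within 250 kb (the conventional window of scoring tools; only the r² value
is dictated by the method). Confounder matching uses 5 quantile bins each
of MAF, distance to the nearest isoform TSS, and LD-proxy count (r² > 0.8);
5 balances matching fidelity against dummy-variable cost and is
configurable. Bins collapse with a warning when values tie.

The enrichment regression is a maximum-likelihood logistic fit; on
non-convergence or runaway coefficients (quasi-complete separation, which
arises legitimately when significant variants concentrate in one confounder
stratum) it falls back to Firth's bias-reduced fit and flags the result.
With no covariates the estimate equals the closed-form 2×2 log odds ratio
to ≥ 6 digits (tested).

Grid-wide significance uses Bonferroni at α / (n_eff × n_thresholds), where
n_eff is the number of leading eigenvalues of the annotation-overlap
correlation matrix needed to reach 99.5% of total variance. Correcting over
thresholds as well as annotations is this package's choice: a
family-wise-error guarantee over the full reported grid is what the
radial-plot style significance flags imply. BH is available via
`correction="bh"`.

## Gene statistic

The SNP-wise mean statistic S_g = Σ z_i², z_i = Φ⁻¹(1 − p_i/2), has null
distribution Σ_j λ_j χ²₁ with λ the eigenvalues of the gene's LD
correlation submatrix. The p-value is computed from that distribution
*exactly*: Ruben's mixture-of-chi-squares series in the body (positive
coefficients give a rigorous truncation bound; tolerance 1e−13), Imhof's
characteristic-function inversion as fallback, and Kuonen's saddlepoint in
the deep tail (beyond absolute 1e−11) where relative accuracy matters. A
two-moment scaled chi-square (Brown/Satterthwaite) was evaluated first and
rejected: at within-block r² = 0.5 its miscalibration is detectable by a
KS test at a few hundred genes (observed deviation ≈ 0.08), which would
spoil null calibration of the whole gene stage. The exact null reduces to
chi-square(k) under identity LD and to the single-SNP p at k = 1, and is
verified against Monte Carlo in tests. Variants are points; a variant in
both an exon and a promoter counts once per gene with both route tags.

Promoter windows are per isoform and strand-aware: for a + strand isoform
with TSS t the window is [t−2000, t); for − strand, (t, t+2000] (upstream =
increasing coordinates). The TSS base itself belongs to the transcript, not
the promoter. Interaction assignment is directional: the variant-side
anchor needs no exon/promoter overlap of its own.

FDR is Benjamini-Hochberg over all tested genes per cell type (pooled
correction available), with the risk set restricted to protein-coding
genes at q < 0.05.

## Scores and evaluation

Weights are the GWAS effect sizes of clumped variants passing the selected
p-threshold; thresholds are scanned over the conventional grid (5e−8 … 1)
and chosen by incremental Nagelkerke R² on the validation cohort, ties to
the smaller threshold. Dosages are counted toward the model's effect
allele, reflecting 2−d on an effect/other swap; any other allele pair is an
error. Missing dosages are mean-imputed to 2·MAF.

Observed R² is the incremental Nagelkerke pseudo-R² of status ~ covariates
+ score over covariates alone. The liability-scale R² applies the
case-control prevalence correction K²(1−K)²/(z²·P(1−P)) to the incremental
*observed-scale* (linear-probability) R², not to Nagelkerke: the
transformation is derived for the 0/1-scale R², and a latent-liability
simulation oracle (planted 3% of liability variance, K = 0.01, balanced
case-control) confirms that choice recovers 0.030 within ±0.002 while the
Nagelkerke-based variant overshoots by ~80%. The transformation is monotone
and zero at zero (tested).

Quantile strata default to edges (0, .05, .25, .45, .65, .85, .95, 1) —
5% tails, 20% body bins, a 10% bin below the top tail — with the reference
being the stratum containing the 0.5 quantile; a score value exactly on a
bin boundary joins the upper stratum. ORs and SEs come from one logistic
regression on stratum dummies plus covariates. The MHC filter removes
chr6:[25 Mb, 35 Mb) — half-open like every other interval; the bounds span
the canonical extended region and are configurable.

Phenotype associations report β on the standardized-score,
standardized-phenotype scale (raw-scale β also emitted); gender enters as a
0/1 dummy, duration in years. Incremental R² equals partial-r² ×
(1 − R²_covariates), the exact identity (tested numerically).

## Canonical studies and problem sizes

`cellrisk.studies` fixes the simulation conditions used by the acceptance
suite and the reproduction script: a 10⁴-cell null enrichment grid (2·10⁴
variants, 5000 random annotations × T ∈ {0.05, 0.01}); one planted-log-OR
recovery run at 2·10⁵ variants (2·10⁴ pruned) plus 100 ranking replicates
at 3·10⁴ variants; gene-null calibration on 2000 single-block genes; gene
recovery over 20 replicates of 10⁴ variants with 30 exonic-route and 30
loop-route causal genes at n_eff = 5·10⁴; liability-R² recovery over 20
case-control cohorts of 10⁴ (K = 0.01, h² = 0.03); phenotype-β recovery
over 10 cohorts of 5000 (β = −0.13); and 100 stratification replicates
(n = 10⁴, score R² = 0.10, prevalence 0.15). Replicate counts and sizes are
chosen so every Monte-Carlo standard error is small against its acceptance
margin while the whole battery runs in minutes on one CPU.

## Known limitations

Block-diagonal LD makes pruning/clumping oracles exact but understates
long-range LD (e.g. across the real MHC). The Firth fallback changes the
estimand slightly (penalized vs ML log-odds) in separated cells — flagged,
not hidden. The liability correction assumes the score is normally
distributed within the population, adequate for polygenic scores but not
for a single large-effect locus. The unique-SNP universes are exactly
disjoint by construction; on real annotations their size (and hence power)
depends on annotation depth, which the generator does not attempt to match.
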