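# cellrisk

Cell-type-aware integration of GWAS summary statistics: regulatory-annotation
enrichment, chromatin-interaction-based gene mapping, and cell-specific
polygenic risk scores (CPRS), with a synthetic-data generator that plants
known truth so every stage is testable without controlled-access data.

## Who this is for

Statistical geneticists and regulatory genomicists who want to ask, for a
complex disease with a published GWAS: *which cell types' open-chromatin
landscape is enriched for the association signal, which genes do the risk
variants act through (including distal variants wired to promoters by
Hi-C/HiChIP loops), and how well does a score restricted to one cell type's
variants stratify disease risk and quantitative phenotypes?*

## The methods at the core

- **Cell-type-specific peaks.** Peaks from all cell types are merged into
  consensus units (≥ 1 bp overlap joins); a unit is *specific* iff it is
  present in at most half of the cell types (inclusive at exactly half), and
  is assigned to every cell type containing it.
- **Enrichment with matched confounders.** Variants are greedily LD-pruned
  (keep the most significant; drop anything with r² > 0.01 within 500 kb of
  a kept variant). For a threshold *T*, fit

  logit P(p_i < T) = α + β·a_i + bins(MAF) + bins(TSS distance) + bins(LD proxies)

  where a_i indicates overlap of the variant (or an r² > 0.8 proxy) with the
  annotation; OR = e^β. The annotation × threshold grid (T from 0.05 down to
  10⁻⁸) is Bonferroni-corrected over the *effective* number of annotations
  (eigenvalues of the annotation-overlap correlation reaching 99.5% of
  variance) times the number of thresholds.
- **Gene mapping.** A variant belongs to a gene if it falls in any isoform's
  exon, in the strand-aware 2-kb window upstream of any isoform TSS, or in a
  loop anchor whose partner anchor overlaps an exon or promoter. The gene
  statistic is the SNP-wise mean S_g = Σ z_i² with z_i = Φ⁻¹(1 − p_i/2); its
  null is the exact weighted chi-square Σ λ_j χ²₁ with λ the eigenvalues of
  the gene's LD submatrix. Risk genes are protein-coding with BH FDR < 0.05.
- **CPRS.** After summary-stat QC (INFO < 0.6, MAF < 1%, missingness > 10%,
  HWE p < 10⁻⁶, kinship > 0.0844) and clumping at r² = 0.1, the score is
  s_j = Σ w_i d_ij over variants annotated to a cell type's gene set (or the
  variants *unique* to it), with the p-threshold chosen on a validation
  cohort. Reported: Nagelkerke incremental R², liability-scale R² adjusted
  for prevalence K (default 0.00127), AUC, and odds ratios across score
  quantile strata (bottom 5%, 20% bins, top 5%) against the median stratum,
  optionally excluding the MHC (chr6:25–35 Mb).
- **Phenotype association.** OLS of standardized phenotype on standardized
  score with age/gender/duration covariates (logistic for binary outcomes
  such as relapse), BH-corrected across the phenotype × universe grid.

## Worked example

```bash
python examples/05_polygenic_score.py
```

prints (30 causal variants planted at h² = 0.15, prevalence 5%, a
2000/2000 case-control cohort):

```
chosen threshold: 0.005 (31 variants)
Nagelkerke R2: 0.238  liability R2: 0.151
AUC: 0.743  association p: 2.65e-132

stratum           OR
q0-0.05          0.09
q0.05-0.25       0.30
q0.25-0.45       0.61
q0.45-0.65       1.00 (reference)
q0.65-0.85       1.79
q0.85-0.95       3.23
q0.95-1          6.18
```

The threshold scan settled on p < 0.005 (capturing all planted signal), the
liability-scale R² recovers the planted heritability ballpark, and risk
rises monotonically across score quantiles with a several-fold elevation in
the top 5% — the qualitative signature this class of cell-specific scores
shows on real cohorts. The other examples (`examples/01`–`06`) walk through
simulation, peak specificity, enrichment, gene mapping and phenotype
association the same way. The shell pipeline mirrors the library:

```bash
cellrisk simulate --config cfg.yaml --seed 7 --out run/
cellrisk peaks --beds run/peaks --out run/specific
cellrisk enrich --stats run/stats.tsv --annotations run/specific \
    --ld run/ld.tsv --genes run/genes.gtf --out run/enrichment.tsv
...
```

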