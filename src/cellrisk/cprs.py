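"""Cell-specific polygenic risk scores (CPRS).

A CPRS is a weighted sum of effect-allele dosages over variants annotated to
one cell type's gene set (optionally only the variants unique to that cell
type), after summary-statistic QC and LD clumping (r2 = 0.1). Evaluation
reports Nagelkerke incremental R2, a prevalence-adjusted liability-scale R2,
AUC, and odds ratios across score quantile strata against the
median-containing stratum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from ._glm import fit_logit, nagelkerke_r2
from .enrichment import prune_variants
from .ld import BlockLDMatrix
from .models import (
    CohortData,
    CPRSResult,
    GeneSnpAnnotation,
    ScoreModel,
    StratumOR,
    SummaryStats,
)

#: p-value thresholds scanned during score optimization
DEFAULT_PRS_THRESHOLDS = (
    5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
)

#: extended MHC region (GRCh37 coordinates), half-open
MHC_REGION = ("chr6", 25_000_000, 35_000_000)

#: default quantile strata: 5% tails, 20% body bins, 10% below the top tail
DEFAULT_STRATA_EDGES = (0.0, 0.05, 0.25, 0.45, 0.65, 0.85, 0.95, 1.0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_pvalues(dosages: pd.DataFrame) -> np.ndarray:
    """One-df chi-square Hardy-Weinberg test on rounded genotype counts."""
    out = np.ones(dosages.shape[1])
    g = np.rint(dosages.to_numpy(dtype=float))
    for j in range(g.shape[1]):
        col = g[:, j]
        col = col[~np.isnan(col)]
        n = len(col)
        if n == 0:
            continue
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        p = (2 * n_bb + n_ab) / (2 * n)
        if p in (0.0, 1.0):
            continue
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([n_aa, n_ab, n_bb])
        chi2 = float(((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum())
        out[j] = sps.chi2.sf(chi2, 1)
    return out


def qc_filter(
    stats: SummaryStats,
    cohort: CohortData | None = None,
    kinship: pd.DataFrame | None = None,
    info_min: float = 0.6,
    maf_min: float = 0.01,
    missing_max: float = 0.10,
    hwe_alpha: float = 1e-6,
    kinship_max: float = 0.0844,
) -> tuple[SummaryStats, CohortData | None, dict]:
    """Variant and individual QC.

    Variants failing INFO < ``info_min``, MAF < ``maf_min``, missingness >
    ``missing_max`` or Hardy-Weinberg p < ``hwe_alpha`` are removed. For each
    related pair (kinship > ``kinship_max``) one member is dropped, keeping
    the individual with higher genotyping completeness (ties by id order).
    """
    t = stats.table
    drop_info = t["info"] < info_min
    drop_maf = t["maf"] < maf_min
    drop_miss = pd.Series(False, index=t.index)
    drop_hwe = pd.Series(False, index=t.index)
    if cohort is not None:
        shared = [v for v in t["variant_id"] if v in cohort.dosages.columns]
        d = cohort.dosages[shared]
        miss = d.isna().mean(axis=0)
        hwe = pd.Series(hwe_pvalues(d), index=shared)
        drop_miss = t["variant_id"].map(miss).fillna(0.0) > missing_max
        drop_hwe = t["variant_id"].map(hwe).fillna(1.0) < hwe_alpha
    drop = drop_info | drop_maf | drop_miss | drop_hwe
    report = {
        "n_info": int(drop_info.sum()),
        "n_maf": int(drop_maf.sum()),
        "n_missing": int(drop_miss.sum()),
        "n_hwe": int(drop_hwe.sum()),
        "n_variants_removed": int(drop.sum()),
        "n_individuals_removed": 0,
    }
    stats_out = SummaryStats(t.loc[~drop].copy(), stats.label)

    cohort_out = cohort
    if cohort is not None and kinship is not None and len(kinship):
        related = kinship[kinship["kinship"] > kinship_max]
        completeness = 1.0 - cohort.dosages.isna().mean(axis=1)
        to_drop: set = set()
        for i1, i2 in related[["id1", "id2"]].itertuples(index=False):
            if i1 in to_drop or i2 in to_drop:
                continue
            c1, c2 = completeness.get(i1, 0.0), completeness.get(i2, 0.0)
            if c1 > c2:
                to_drop.add(i2)
            elif c2 > c1:
                to_drop.add(i1)
            else:
                to_drop.add(max(i1, i2))  # tie: keep the first by id order
        keep = [i for i in cohort.dosages.index if i not in to_drop]
        pos = [cohort.dosages.index.get_loc(i) for i in keep]
        cohort_out = CohortData(
            dosages=cohort.dosages.loc[keep],
            status=cohort.status[pos],
            phenotypes=cohort.phenotypes.iloc[pos],
            covariates=cohort.covariates.iloc[pos],
            variant_alleles=cohort.variant_alleles,
            true_score=None if cohort.true_score is None else cohort.true_score[pos],
        )
        report["n_individuals_removed"] = len(to_drop)
    return stats_out, cohort_out, report


# ---------------------------------------------------------------------------
# variant universes / clumping / MHC
# ---------------------------------------------------------------------------


def restrict_universe(
    annotations: dict[str, GeneSnpAnnotation],
    cell_type: str | None,
    mode: str = "all",
) -> set[str]:
    """Variant universe for scoring.

    all       variants annotated to any gene of ``cell_type``;
    unique    that set minus the union over all other cell types;
    combined  the union over every cell type (``cell_type`` ignored).
    """
    if mode == "combined":
        out: set[str] = set()
        for ann in annotations.values():
            out |= ann.all_variants()
    elif mode in ("all", "unique"):
        if cell_type not in annotations:
            raise ValueError(f"no annotation for cell type {cell_type!r}")
        out = annotations[cell_type].all_variants()
        if mode == "unique":
            others: set[str] = set()
            for ct, ann in annotations.items():
                if ct != cell_type:
                    others |= ann.all_variants()
            out = out - others
    else:
        raise ValueError(f"unknown universe mode {mode!r}")
    if not out:
        raise ValueError(f"empty variant universe (cell_type={cell_type}, mode={mode})")
    return out


def clump(
    stats: SummaryStats,
    ld: BlockLDMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> np.ndarray:
    """Greedy clumping for score construction: same contract as pruning, with
    r2 = 0.1 to retain only independent effects."""
    return prune_variants(stats, ld, r2_threshold, window_kb)


def exclude_mhc(
    stats: SummaryStats, region: tuple[str, int, int] = MHC_REGION
) -> SummaryStats:
    """Remove variants inside the (extended) MHC region, half-open bounds."""
    chrom, start, end = region
    t = stats.table
    inside = (t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] < end)
    return SummaryStats(t.loc[~inside].copy(), stats.label)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def compute_prs(cohort: CohortData, model: ScoreModel) -> np.ndarray:
    """Per-individual weighted sum of effect-allele dosages.

    The cohort codes dosages toward its own effect allele; when the score
    model's effect allele is the cohort's other allele the dosage is
    reflected (2 - d). Any other allele combination is an error. Missing
    dosages are mean-imputed to 2 * MAF.
    """
    if cohort.variant_alleles is None:
        raise ValueError("cohort lacks variant allele metadata")
    meta = cohort.variant_alleles.set_index("variant_id")
    missing = [v for v in model.variant_ids if v not in cohort.dosages.columns]
    if missing:
        raise ValueError(f"variants absent from dosage matrix: {missing[:5]}...")
    score = np.zeros(cohort.n)
    mismatched = []
    for vid, w, ea in zip(model.variant_ids, model.weights, model.effect_alleles):
        row = meta.loc[vid]
        d = cohort.dosages[vid].to_numpy(dtype=float)
        d = np.where(np.isnan(d), 2.0 * row["maf"], d)
        if ea == row["effect_allele"]:
            score += w * d
        elif ea == row["other_allele"]:
            score += w * (2.0 - d)
        else:
            mismatched.append(vid)
    if mismatched:
        raise ValueError(f"effect-allele mismatch for variants: {mismatched[:10]}")
    return score


def build_score_model(
    stats: SummaryStats,
    ld: BlockLDMatrix,
    p_threshold: float,
    universe: set[str] | None = None,
    cell_type: str = "combined",
    snp_universe: str = "all_cell_snps",
    mhc_excluded: bool = False,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
) -> ScoreModel:
    """Clump within the universe, keep variants with p < threshold, and take
    their GWAS effect sizes as weights."""
    t = stats.table
    if universe is not None:
        mask = t["variant_id"].isin(universe).to_numpy()
    else:
        mask = np.ones(len(t), dtype=bool)
    idx_universe = np.nonzero(mask)[0]
    sub = stats.subset(idx_universe)
    sub_ld = _subset_ld(ld, idx_universe)
    kept_local = clump(sub, sub_ld, clump_r2, clump_window_kb)
    sel = sub.table.iloc[kept_local]
    sel = sel[sel["p"] < p_threshold]
    return ScoreModel(
        variant_ids=sel["variant_id"].to_numpy(),
        weights=sel["beta"].to_numpy(),
        effect_alleles=sel["effect_allele"].to_numpy(),
        p_threshold=p_threshold,
        cell_type=cell_type,
        snp_universe=snp_universe,
        mhc_excluded=mhc_excluded,
    )


def _subset_ld(ld: BlockLDMatrix, idx: np.ndarray) -> BlockLDMatrix:
    """LD restricted to a sorted index subset, preserving block structure."""
    idx = np.asarray(idx)
    starts, blocks = [], []
    offset = 0
    for s, block in zip(ld.block_starts, ld.blocks):
        local = idx[(idx >= s) & (idx < s + block.shape[0])] - s
        if local.size == 0:
            continue
        starts.append(offset)
        blocks.append(block[np.ix_(local, local)])
        offset += local.size
    if not blocks:
        return BlockLDMatrix(np.array([], dtype=int), [])
    return BlockLDMatrix(np.array(starts), blocks)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])


def liability_r2(r2_observed_scale: float, K: float, P: float) -> float:
    """Observed-scale (0/1) R2 -> liability-scale R2 under case-control
    ascertainment: multiply by K^2 (1-K)^2 / (z^2 P (1-P)) with z the normal
    density at the prevalence quantile. Monotone in the input and 0 at 0."""
    z = sps.norm.pdf(sps.norm.ppf(1 - K))
    c = K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    return float(max(r2_observed_scale * c, 0.0))


def evaluate(
    scores: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    prevalence: float = 0.00127,
    threshold: float = float("nan"),
) -> CPRSResult:
    """Score performance on a case-control cohort.

    * observed R2: incremental Nagelkerke pseudo-R2 of the logistic model
      status ~ covariates + score over covariates alone;
    * liability R2: the incremental observed-scale (linear-model) R2 mapped to
      the liability scale with the prevalence correction (the transformation
      is derived for the 0/1-scale R2, so that is what it is applied to);
    * AUC: rank discrimination of the score alone;
    * association p: two-sided Wald test on the score coefficient.
    """
    status = np.asarray(status, dtype=float)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(status)
    if len(classes) < 2:
        raise ValueError("status must contain both cases and controls")
    n = len(status)
    Xc = _covariate_matrix(covariates, n)
    Xf = np.column_stack([Xc, scores])

    fit_cov = fit_logit(Xc, status)
    fit_full = fit_logit(Xf, status)
    r2_cov = nagelkerke_r2(fit_cov.llf, fit_cov.llnull, n)
    r2_full = nagelkerke_r2(fit_full.llf, fit_full.llnull, n)
    r2_obs = max(r2_full - r2_cov, 0.0)

    # observed-scale incremental R2 for the liability transformation
    lin_cov = sm.OLS(status, Xc).fit()
    lin_full = sm.OLS(status, Xf).fit()
    r2_lin = max(lin_full.rsquared - lin_cov.rsquared, 0.0)
    P = float(status.mean())
    r2_liab = liability_r2(r2_lin, prevalence, P)

    auc = float(roc_auc_score(status, scores))
    p_assoc = float(fit_full.pvalues[-1])
    return CPRSResult(
        threshold=threshold,
        r2_observed=r2_obs,
        r2_liability=r2_liab,
        auc=auc,
        p_association=p_assoc,
        n=n,
    )


def optimize_threshold(
    stats: SummaryStats,
    ld: BlockLDMatrix,
    cohort: CohortData,
    covariates: pd.DataFrame | None = None,
    thresholds: tuple[float, ...] = DEFAULT_PRS_THRESHOLDS,
    universe: set[str] | None = None,
    cell_type: str = "combined",
    snp_universe: str = "all_cell_snps",
    prevalence: float = 0.00127,
) -> tuple[ScoreModel, pd.DataFrame]:
    """Scan p-value thresholds on a validation cohort; return the model with
    the highest incremental Nagelkerke R2 (ties -> smaller threshold)."""
    rows = []
    best: tuple[float, float, ScoreModel] | None = None
    for t in sorted(thresholds):
        model = build_score_model(
            stats, ld, t, universe, cell_type=cell_type, snp_universe=snp_universe
        )
        if len(model.variant_ids) == 0:
            warnings.warn(f"no variants at threshold {t}; skipped")
            continue
        score = compute_prs(cohort, model)
        if np.std(score) == 0:
            warnings.warn(f"constant score at threshold {t}; skipped")
            continue
        res = evaluate(score, cohort.status, covariates, prevalence, threshold=t)
        rows.append(
            {
                "threshold": t,
                "n_variants": len(model.variant_ids),
                "r2_observed": res.r2_observed,
                "r2_liability": res.r2_liability,
                "auc": res.auc,
            }
        )
        # strict > keeps the smallest threshold on exact ties
        if best is None or res.r2_observed > best[0]:
            best = (res.r2_observed, t, model)
    if best is None:
        raise ValueError("no threshold produced a scoreable model")
    return best[2], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quantile stratification
# ---------------------------------------------------------------------------


def stratify_or(
    scores: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    edges: tuple[float, ...] = DEFAULT_STRATA_EDGES,
) -> list[StratumOR]:
    """Odds ratios per score quantile stratum versus the median stratum.

    Logistic regression of status on stratum dummies (+ covariates); the
    reference is the stratum containing the 0.5 quantile. Empty strata are
    dropped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=float)
    edges = tuple(edges)
    if edges[0] != 0.0 or edges[-1] != 1.0 or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("strata must cover [0, 1] with increasing edges")
    cuts = np.quantile(scores, edges[1:-1])
    assign = np.searchsorted(cuts, scores, side="right")
    n_strata = len(edges) - 1
    ref = int(np.searchsorted(cuts, np.quantile(scores, 0.5), side="right"))

    present = [s for s in range(n_strata) if np.any(assign == s)]
    if len(present) < n_strata:
        warnings.warn("empty strata dropped")
    non_ref = [s for s in present if s != ref]
    dummies = np.column_stack([(assign == s).astype(float) for s in non_ref])
    Xc = _covariate_matrix(covariates, len(status))
    X = np.column_stack([Xc, dummies])
    fit = fit_logit(X, status)
    k0 = Xc.shape[1]

    out = []
    for pos, s in enumerate(non_ref):
        beta = float(fit.params[k0 + pos])
        se = float(fit.bse[k0 + pos])
        mask = assign == s
        out.append(
            StratumOR(
                stratum=f"q{edges[s]:g}-{edges[s + 1]:g}",
                lo_quantile=edges[s],
                hi_quantile=edges[s + 1],
                n_cases=int(status[mask].sum()),
                n_controls=int((1 - status[mask]).sum()),
                odds_ratio=float(np.exp(beta)),
                se_log_or=se,
            )
        )
    mask = assign == ref
    out.append(
        StratumOR(
            stratum=f"q{edges[ref]:g}-{edges[ref + 1]:g}",
            lo_quantile=edges[ref],
            hi_quantile=edges[ref + 1],
            n_cases=int(status[mask].sum()),
            n_controls=int((1 - status[mask]).sum()),
            odds_ratio=1.0,
            se_log_or=0.0,
            is_reference=True,
        )
    )
    out.sort(key=lambda s: s.lo_quantile)
    return out
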