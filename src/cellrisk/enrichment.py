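"""Enrichment of GWAS associations within regulatory annotations.

The analysis mirrors the GARFIELD design: variants are greedily LD-pruned
(most significant first), association is dichotomized at a GWAS p-value
threshold T, and a logistic regression of the significance indicator on the
annotation indicator — adjusted for categorical bins of minor allele
frequency, distance to the nearest TSS, and LD-proxy count — yields a
log-odds enrichment estimate whose exponential is the reported odds ratio.
Multiple testing over the annotation x threshold grid is controlled by
Bonferroni over the effective number of independent annotations (eigenvalue
rule) times the number of thresholds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._glm import fit_logit
from .ld import BlockLDMatrix
from .models import AnnotationMatrix, EnrichmentResult, Gene, SummaryStats

#: the eight GWAS p-value thresholds scanned by default
DEFAULT_THRESHOLDS = (0.05, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def prune_variants(
    stats: SummaryStats,
    ld: BlockLDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 500.0,
) -> np.ndarray:
    """Greedy LD pruning in ascending GWAS p order.

    A variant is kept iff no already-kept variant within ``window_kb`` (on the
    same chromosome) has r2 above ``r2_threshold`` with it. Returns the sorted
    indices of kept variants. Ties on p break by position for determinism.
    """
    p = stats.p
    pos = stats.pos
    chrom = stats.chrom
    order = np.lexsort((pos, p))  # ascending p, ties by position
    window = window_kb * 1000.0
    kept_mask = np.zeros(len(p), dtype=bool)
    for i in order:
        ok = True
        for j in ld.neighbors(i, r2_threshold):
            if kept_mask[j] and chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window:
                ok = False
                break
        if ok:
            kept_mask[i] = True
    return np.nonzero(kept_mask)[0]


def tss_distances(stats: SummaryStats, genes: list[Gene]) -> np.ndarray:
    """Distance to the nearest isoform TSS over all genes, per variant."""
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        for iso in g.isoforms:
            tss_by_chrom.setdefault(g.chrom, []).append(iso.tss)
    if not tss_by_chrom:
        raise ValueError("no TSS available: gene models are empty")
    out = np.full(len(stats), np.inf)
    chrom = stats.chrom
    pos = stats.pos
    for c, tss_list in tss_by_chrom.items():
        sel = chrom == c
        if not sel.any():
            continue
        tss = np.sort(np.asarray(tss_list))
        k = np.searchsorted(tss, pos[sel])
        left = np.where(k > 0, np.abs(pos[sel] - tss[np.clip(k - 1, 0, None)]), np.inf)
        right = np.where(
            k < len(tss), np.abs(tss[np.clip(k, None, len(tss) - 1)] - pos[sel]), np.inf
        )
        out[sel] = np.minimum(left, right)
    return out


def _quantile_codes(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin codes; collapses (with a warning) when values tie heavily."""
    ser = pd.Series(values)
    if ser.nunique() < n_bins:
        warnings.warn(
            f"only {ser.nunique()} distinct values for {n_bins} bins; bins collapse"
        )
    codes = pd.qcut(ser.rank(method="first"), q=min(n_bins, ser.nunique()), labels=False)
    return codes.to_numpy()


def bin_confounders(
    stats: SummaryStats,
    genes: list[Gene],
    ld_proxy_counts: np.ndarray,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Categorical matching bins for MAF, TSS distance and LD-proxy count."""
    maf = stats.table["maf"].to_numpy()
    dist = tss_distances(stats, genes)
    return pd.DataFrame(
        {
            "maf_bin": _quantile_codes(maf, n_bins),
            "tss_bin": _quantile_codes(dist, n_bins),
            "ldprox_bin": _quantile_codes(np.asarray(ld_proxy_counts, dtype=float), n_bins),
        },
        index=range(len(stats)),
    )


def test_enrichment(
    stats: SummaryStats,
    annotation: np.ndarray,
    threshold: float,
    bins: pd.DataFrame | None = None,
    annotation_id: str = "annotation",
) -> EnrichmentResult:
    """Logistic regression of 1{p < T} on the annotation indicator.

    Confounder bins enter as dummy-coded categorical covariates. Cells with
    no significant (or no non-significant) variants are flagged untestable.
    Separation triggers the Firth-penalized fallback, recorded in ``method``.
    """
    y = (stats.p < threshold).astype(float)
    a = np.asarray(annotation, dtype=float)
    n_sig = int(y.sum())
    n_annot = int(a.sum())
    base = EnrichmentResult(
        annotation_id=annotation_id,
        threshold=threshold,
        estimate=None,
        se=None,
        p=None,
        n_pruned=len(y),
        n_significant=n_sig,
        n_annotated=n_annot,
        testable=False,
    )
    if n_sig == 0 or n_sig == len(y) or n_annot == 0 or n_annot == len(y):
        return base
    cols = [np.ones(len(y)), a]
    if bins is not None:
        for feature in bins.columns:
            dummies = pd.get_dummies(bins[feature], drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    fit = fit_logit(X, y)
    return EnrichmentResult(
        annotation_id=annotation_id,
        threshold=threshold,
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n_pruned=len(y),
        n_significant=n_sig,
        n_annotated=n_annot,
        testable=True,
        method=fit.method,
    )


def effective_n_annotations(values: np.ndarray, variance_frac: float = 0.995) -> int:
    """Effective number of independent annotations.

    The count of leading eigenvalues of the annotation-overlap correlation
    matrix needed to reach ``variance_frac`` of the total variance. Constant
    columns carry no information and are dropped first.
    """
    v = np.asarray(values, dtype=float)
    keep = v.std(axis=0) > 0
    v = v[:, keep]
    if v.shape[1] == 0:
        return 1
    corr = np.corrcoef(v, rowvar=False)
    corr = np.atleast_2d(corr)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0, None)
    cum = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(cum, variance_frac) + 1)


def run_enrichment_scan(
    stats: SummaryStats,
    annotations: AnnotationMatrix,
    ld: BlockLDMatrix,
    genes: list[Gene],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_bins: int = 5,
    alpha: float = 0.05,
    correction: str = "eff_bonferroni",
    prune_r2: float = 0.01,
    prune_window_kb: float = 500.0,
) -> list[EnrichmentResult]:
    """Full annotation x threshold enrichment grid with multiple-testing flags.

    ``annotations.values`` must be aligned to ``stats`` rows (one indicator
    column per annotation, computed with or without LD proxies upstream).
    ``correction`` is ``eff_bonferroni`` (default) or ``bh``.
    """
    if annotations.values.shape[1] < 1:
        raise ValueError("need at least one annotation")
    kept = prune_variants(stats, ld, prune_r2, prune_window_kb)
    sub = stats.subset(kept)
    proxy_counts = ld.proxy_counts(0.8)[kept]
    bins = bin_confounders(sub, genes, proxy_counts, n_bins)
    values = annotations.values[kept]

    results: list[EnrichmentResult] = []
    for ci, ann_id in enumerate(annotations.annotation_ids):
        for t in thresholds:
            results.append(
                test_enrichment(sub, values[:, ci], t, bins, annotation_id=ann_id)
            )

    tested = [r for r in results if r.testable]
    if tested:
        if correction == "eff_bonferroni":
            n_eff = effective_n_annotations(values)
            cut = alpha / (n_eff * len(thresholds))
            for r in tested:
                r.significant_after_correction = r.p < cut
        elif correction == "bh":
            from ._glm import bh_flags

            flags = bh_flags(np.array([r.p for r in tested]), alpha)
            for r, f in zip(tested, flags):
                r.significant_after_correction = bool(f)
        else:
            raise ValueError(f"unknown correction {correction!r}")
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "annotation_id": r.annotation_id,
                "threshold": r.threshold,
                "estimate": r.estimate,
                "se": r.se,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "n_pruned": r.n_pruned,
                "n_significant": r.n_significant,
                "n_annotated": r.n_annotated,
                "testable": r.testable,
                "method": r.method,
                "significant_after_correction": r.significant_after_correction,
            }
        )
    return pd.DataFrame(rows)
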