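"""Canonical simulation studies: null calibration and parameter recovery.

Each function generates synthetic data with the study's planted truth, runs
the relevant pipeline stage end to end, and returns the measured quantities
together with the planted values. The defaults are the study conditions;
tests and the reproduction script call these functions rather than redefining
designs of their own.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import annotation as ann_mod
from . import cprs as cprs_mod
from . import enrichment as enr_mod
from . import gene_mapping as gm_mod
from . import phenotype_assoc as pa_mod
from . import synthio
from .models import AnnotationMatrix, InteractionSet, ScoreModel


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# enrichment: null calibration and planted recovery
# ---------------------------------------------------------------------------


def enrichment_null_calibration(
    seed: int,
    n_variants: int = 20_000,
    block_size: int = 5,
    n_genes: int = 400,
    n_annotations: int = 5_000,
    thresholds: tuple[float, ...] = (0.05, 0.01),
    annotation_rate: float = 0.3,
    n_eff: float = 5e4,
) -> dict:
    """Fully null GWAS against random annotations: the fraction of grid cells
    with enrichment p < 0.05 should sit at the nominal 5%."""
    s = _child_seeds(seed, 3)
    genome = synthio.generate_genome(
        synthio.GenomeConfig(n_variants=n_variants, block_size=block_size, n_genes=n_genes),
        s[0],
    )
    truth = synthio.make_truth(genome, s[1])
    stats = synthio.generate_gwas(genome, truth, n_eff, s[2])
    rng = np.random.default_rng(s[2] + 1)
    values = (rng.random((n_variants, n_annotations)) < annotation_rate).astype(np.int8)
    am = AnnotationMatrix(
        stats.variant_ids, [f"a{i:05d}" for i in range(n_annotations)], values
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = enr_mod.run_enrichment_scan(
            stats, am, genome.ld, genome.genes, thresholds=thresholds
        )
    p = np.array([r.p for r in results if r.testable])
    return {
        "fraction_significant": float((p < 0.05).mean()),
        "n_cells": int(p.size),
    }


def _planted_enrichment_run(
    seed: int,
    n_variants: int,
    n_causal: int,
    causal_beta: float,
    log_or: float,
    threshold: float,
    n_cell_types: int,
    n_eff: float,
) -> dict:
    s = _child_seeds(seed, 4)
    genome = synthio.generate_genome(
        synthio.GenomeConfig(
            n_variants=n_variants, block_size=10, n_genes=max(n_variants // 100, 20)
        ),
        s[0],
    )
    truth = synthio.make_truth(
        genome,
        s[1],
        n_causal_variants=n_causal,
        causal_beta=causal_beta,
        enriched_annotations={"cell0": log_or},
        plant_threshold=threshold,
    )
    stats = synthio.generate_gwas(genome, truth, n_eff, s[2])
    peaks, _ = synthio.generate_annotations(
        genome,
        synthio.AnnotationConfig(n_cell_types=n_cell_types, n_background_peaks=0),
        s[3],
        truth=truth,
        stats=stats,
    )
    am = ann_mod.build_annotation_matrix(stats, peaks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = enr_mod.run_enrichment_scan(
            stats, am, genome.ld, genome.genes, thresholds=(threshold,)
        )
    by_cell = {r.annotation_id: r for r in results if r.testable}
    target = by_cell["cell0"]
    rank_first = all(
        target.estimate >= r.estimate for c, r in by_cell.items() if c != "cell0"
    )
    return {
        "estimate": float(target.estimate),
        "se": float(target.se),
        "odds_ratio": float(target.odds_ratio),
        "n_pruned": int(target.n_pruned),
        "rank_first": bool(rank_first),
    }


def enrichment_recovery(
    seed: int,
    n_variants: int = 200_000,
    n_causal: int = 1_000,
    causal_beta: float = 0.045,
    log_or: float = float(np.log(2)),
    threshold: float = 1e-5,
    n_cell_types: int = 5,
    n_eff: float = 5e4,
) -> dict:
    """One large run: planted log-OR = log 2 on 'cell0', >= 2e4 pruned
    variants; returns the estimate, its SE, and the absolute z-error."""
    out = _planted_enrichment_run(
        seed, n_variants, n_causal, causal_beta, log_or, threshold, n_cell_types, n_eff
    )
    out["planted_log_or"] = log_or
    out["z_error"] = abs(out["estimate"] - log_or) / out["se"]
    return out


def enrichment_rank_replicates(
    seed: int,
    n_reps: int = 100,
    n_variants: int = 30_000,
    n_causal: int = 300,
    causal_beta: float = 0.045,
    log_or: float = float(np.log(2)),
    threshold: float = 1e-5,
    n_cell_types: int = 5,
    n_eff: float = 5e4,
) -> dict:
    """Replicated smaller runs: how often the planted cell type attains the
    largest enrichment among all cell types."""
    wins = 0
    for s in _child_seeds(seed, n_reps):
        r = _planted_enrichment_run(
            s, n_variants, n_causal, causal_beta, log_or, threshold, n_cell_types, n_eff
        )
        wins += r["rank_first"]
    return {"rank_first_fraction": wins / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# gene mapping: null calibration and planted recovery
# ---------------------------------------------------------------------------


def gene_null_calibration(
    seed: int,
    n_genes: int = 2_000,
    block_size: int = 5,
    with_ld: bool = True,
    n_eff: float = 5e4,
) -> dict:
    """Null gene-level p-values should be uniform, with and without
    within-block LD (pairwise r2 = 0.5)."""
    s = _child_seeds(seed, 3)
    cfg = synthio.GenomeConfig(
        n_variants=n_genes * block_size,
        block_size=block_size,
        n_genes=n_genes,
        ld_profile="exchangeable",
        ld_rho=float(np.sqrt(0.5)) if with_ld else 0.0,
    )
    genome = synthio.generate_genome(cfg, s[0])
    truth = synthio.make_truth(genome, s[1])
    stats = synthio.generate_gwas(genome, truth, n_eff, s[2])
    ann = gm_mod.build_location_annotation(stats, genome.genes)
    results = gm_mod.gene_level_test(stats, ann, genome.ld, genome.genes)
    p = np.array([r.p for r in results])
    ks = sps.kstest(p, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_genes": int(p.size)}


def _gene_recovery_run(
    seed: int,
    n_variants: int,
    n_genes: int,
    n_exonic_causal: int,
    n_loop_causal: int,
    causal_beta: float,
    n_eff: float,
) -> dict:
    s = _child_seeds(seed, 4)
    genome = synthio.generate_genome(
        synthio.GenomeConfig(
            n_variants=n_variants, block_size=10, n_genes=n_genes,
            spacing_mean_bp=3000,
        ),
        s[0],
    )
    # exonic-route causal genes via the generic planting path
    truth = synthio.make_truth(
        genome, s[1], n_causal_genes=n_exonic_causal, causal_beta=causal_beta
    )
    # loop-route causal genes: the causal variant sits in a gene-free LD
    # block and reaches its gene only through a chromatin loop
    rng = np.random.default_rng(s[2])
    ld = genome.ld
    gene_blocks = set(range(n_genes))  # genes occupy the first n_genes blocks
    free_blocks = [b for b in range(ld.n_blocks) if b not in gene_blocks]
    coding = [
        g for g in genome.genes
        if g.biotype == "protein_coding" and g.gene_id not in truth.causal_genes
    ]
    chosen_genes = rng.choice(len(coding), size=n_loop_causal, replace=False)
    chosen_blocks = rng.choice(len(free_blocks), size=n_loop_causal, replace=False)
    pos = genome.variants["pos"].to_numpy()
    chrom = genome.variants["chrom"].iloc[0]
    loop_rows = []
    for gi, bi in zip(chosen_genes, chosen_blocks):
        gene = coding[gi]
        block = free_blocks[bi]
        v = int(rng.choice(ld.blockmates(ld.block_starts[block])))
        vid = genome.variants["variant_id"].iloc[v]
        truth.causal_variants[vid] = causal_beta * (1 if rng.random() < 0.5 else -1)
        truth.causal_genes.add(gene.gene_id)
        tss = gene.isoforms[0].tss
        loop_rows.append(
            (chrom, max(tss - 500, 0), tss + 500, chrom, int(pos[v]) - 500, int(pos[v]) + 500, 1.0)
        )
    # background loops: non-causal genes to variants in gene-free blocks
    other_free = [free_blocks[b] for b in range(len(free_blocks)) if b not in set(chosen_blocks)]
    non_causal = [g for g in genome.genes if g.gene_id not in truth.causal_genes]
    for _ in range(100):
        gene = non_causal[int(rng.integers(len(non_causal)))]
        block = other_free[int(rng.integers(len(other_free)))]
        v = int(rng.choice(ld.blockmates(ld.block_starts[block])))
        tss = gene.isoforms[0].tss
        loop_rows.append(
            (chrom, max(tss - 500, 0), tss + 500, chrom, int(pos[v]) - 500, int(pos[v]) + 500, 1.0)
        )
    loops = InteractionSet(
        "hic",
        pd.DataFrame(
            loop_rows,
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"],
        ),
    )

    stats = synthio.generate_gwas(genome, truth, n_eff, s[3])
    loc = gm_mod.build_location_annotation(stats, genome.genes)
    inter = gm_mod.build_interaction_annotation(stats, genome.genes, loops)
    merged = gm_mod.merge_annotations(loc, inter)
    results = gm_mod.gene_level_test(stats, merged, ld, genome.genes)
    risk = gm_mod.fdr_filter(results, 0.05)
    causal = truth.causal_genes
    tp = len(risk & causal)
    return {
        "sensitivity": tp / len(causal),
        "fdr": (len(risk) - tp) / max(len(risk), 1),
        "n_risk": len(risk),
    }


def gene_recovery(
    seed: int,
    n_reps: int = 20,
    n_variants: int = 10_000,
    n_genes: int = 500,
    n_exonic_causal: int = 30,
    n_loop_causal: int = 30,
    causal_beta: float = 0.05,
    n_eff: float = 5e4,
) -> dict:
    """Planted causal genes (exonic and loop-mediated routes) recovered at
    q < 0.05: average sensitivity and observed FDR over replicates."""
    sens, fdr = [], []
    for s in _child_seeds(seed, n_reps):
        r = _gene_recovery_run(
            s, n_variants, n_genes, n_exonic_causal, n_loop_causal, causal_beta, n_eff
        )
        sens.append(r["sensitivity"])
        fdr.append(r["fdr"])
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# scores: liability R2, stratification, phenotype association
# ---------------------------------------------------------------------------


def liability_r2_recovery(
    seed: int,
    n_reps: int = 20,
    h2: float = 0.03,
    prevalence: float = 0.01,
    n_cases: int = 5_000,
    n_controls: int = 5_000,
    n_variants: int = 50,
    n_causal: int = 10,
) -> dict:
    """Case-control cohorts under a liability-threshold model; the true-weight
    polygenic score should recover the planted liability-scale variance."""
    vals = []
    aucs = []
    for s in _child_seeds(seed, n_reps):
        ss = _child_seeds(s, 3)
        genome = synthio.generate_genome(
            synthio.GenomeConfig(n_variants=n_variants, block_size=5, n_genes=5), ss[0]
        )
        truth = synthio.make_truth(
            genome, ss[1], n_causal_variants=n_causal, causal_beta=1.0,
            heritability=h2, prevalence=prevalence,
        )
        cohort = synthio.generate_cohort(
            genome, truth, ss[2], sampling="case_control",
            n_cases=n_cases, n_controls=n_controls,
        )
        ids = sorted(truth.causal_variants)
        meta = genome.variants.set_index("variant_id")
        model = ScoreModel(
            np.array(ids),
            np.array([truth.causal_variants[v] for v in ids]),
            meta.loc[ids, "effect_allele"].to_numpy(),
            1.0,
        )
        score = cprs_mod.compute_prs(cohort, model)
        res = cprs_mod.evaluate(score, cohort.status, None, prevalence)
        vals.append(res.r2_liability)
        aucs.append(res.auc)
    return {
        "r2_liability": float(np.mean(vals)),
        "planted_h2": h2,
        "auc": float(np.mean(aucs)),
        "n_reps": n_reps,
    }


def strata_monotonicity(
    seed: int,
    n_reps: int = 100,
    n: int = 10_000,
    score_r2: float = 0.10,
    prevalence: float = 0.15,
) -> dict:
    """Quantile odds ratios under a planted score effect: Spearman-monotone
    strata with the top bin exceeding the reference."""
    wins = 0
    top_ors = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        score = rng.standard_normal(n)
        liab = np.sqrt(score_r2) * score + np.sqrt(1 - score_r2) * rng.standard_normal(n)
        status = (liab > sps.norm.ppf(1 - prevalence)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata = cprs_mod.stratify_or(score, status)
        ors = [s_.odds_ratio for s_ in strata]  # sorted by quantile
        rho = sps.spearmanr(np.arange(len(ors)), ors).statistic
        top = strata[-1]
        top_ors.append(top.odds_ratio)
        if rho > 0 and top.odds_ratio > 1.0:
            wins += 1
    return {
        "monotone_fraction": wins / n_reps,
        "top_stratum_or": float(np.mean(top_ors)),
        "n_reps": n_reps,
    }


def phenotype_beta_recovery(
    seed: int,
    n_reps: int = 10,
    beta: float = -0.13,
    n: int = 5_000,
    h2: float = 0.3,
) -> dict:
    """Planted standardized effect of the genetic score on a quantitative
    phenotype, recovered by covariate-adjusted OLS."""
    betas = []
    r2s = []
    for s in _child_seeds(seed, n_reps):
        ss = _child_seeds(s, 3)
        genome = synthio.generate_genome(
            synthio.GenomeConfig(n_variants=50, block_size=5, n_genes=5), ss[0]
        )
        truth = synthio.make_truth(
            genome, ss[1], n_causal_variants=10, causal_beta=1.0,
            heritability=h2, prevalence=0.2, phenotype_effects={"wmv": beta},
        )
        cohort = synthio.generate_cohort(
            genome, truth, ss[2], sampling="population", n_individuals=n
        )
        res = pa_mod.assoc_linear(
            cohort.true_score,
            cohort.phenotypes["wmv"].to_numpy(),
            cohort.covariates[["age", "gender", "duration"]],
            phenotype_name="wmv",
        )
        betas.append(res.beta)
        r2s.append(res.r2_incremental)
    return {
        "beta": float(np.mean(betas)),
        "planted_beta": beta,
        "r2_incremental": float(np.mean(r2s)),
        "n_reps": n_reps,
    }
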