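"""Synthetic genomes, annotations, loops, GWAS summary statistics and cohorts.

Everything downstream of this module is exercised on data produced here, with
the planted truth (enriched cell types, causal genes, effect sizes,
heritability) recorded so recovery tests can compare estimates against known
parameters.

Model sketch
------------
* Variants live on one chromosome in disjoint LD blocks. Within a block the
  signed correlation is either exchangeable (constant rho) or AR(1)-decaying
  (rho**|i-j|); the sign of r(i,j) is s_i * s_j for a per-variant sign vector,
  which keeps every block matrix positive semi-definite.
* GWAS Z-scores are drawn per block from a multivariate normal whose
  correlation is the signed LD and whose mean is the LD-propagated
  non-centrality  mean_i = sum_j r_ij * beta_j * sqrt(2*maf_j*(1-maf_j)*n_eff).
* Genotypes come from a Gaussian copula: two haplotype latents per individual
  with the block correlation, thresholded at the (1-MAF) normal quantile, so
  marginal dosages are exactly Binomial(2, MAF).
* Case/control status follows a liability-threshold model: liability =
  genetic score + N(0, 1-h2), case iff liability > Phi^-1(1-K).
* Quantitative phenotypes are planted as beta * (standardized genetic score)
  plus small covariate effects plus noise, total variance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld import BlockLDMatrix
from .models import (
    CohortData,
    Gene,
    GenomeModel,
    InteractionSet,
    Isoform,
    PeakSet,
    SummaryStats,
    SyntheticTruth,
)

RIDGE = 1e-6  # added to near-singular LD diagonals before Cholesky

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    n_variants: int = 1000
    block_size: int = 10
    chrom: str = "chr1"
    spacing_min_bp: int = 200
    spacing_mean_bp: int = 2000
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_profile: str = "decaying"  # 'decaying' (AR1) or 'exchangeable'
    ld_rho: float = 0.9
    n_genes: int = 50
    coding_fraction: float = 0.8
    max_isoforms: int = 2

    def validate(self) -> None:
        if self.n_variants < 1 or self.block_size < 1:
            raise ValueError("n_variants and block_size must be >= 1")
        if not 0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")
        if self.ld_profile not in ("decaying", "exchangeable"):
            raise ValueError(f"unknown ld_profile {self.ld_profile!r}")
        if not 0 <= self.ld_rho <= 1:
            raise ValueError("ld_rho must lie in [0, 1]")
        if self.spacing_min_bp < 1 or self.spacing_mean_bp < self.spacing_min_bp:
            raise ValueError("invalid spacing parameters")


@dataclass
class AnnotationConfig:
    n_cell_types: int = 6
    n_background_peaks: int = 100
    background_width_bp: int = 500
    sharing: object = "mixed"  # 'unique' | 'ubiquitous' | 'mixed' | {count: prob}
    variant_peak_rate: float = 0.2  # per-cell-type baseline P(variant in a peak)

    def sharing_probs(self, n_cell_types: int) -> np.ndarray:
        """Probability over membership counts 1..n_cell_types."""
        if self.sharing == "unique":
            p = np.zeros(n_cell_types)
            p[0] = 1.0
        elif self.sharing == "ubiquitous":
            p = np.zeros(n_cell_types)
            p[-1] = 1.0
        elif self.sharing == "mixed":
            # geometric-ish decay: most peaks specific, few ubiquitous
            p = 0.5 ** np.arange(n_cell_types)
            p /= p.sum()
        elif isinstance(self.sharing, dict):
            p = np.zeros(n_cell_types)
            for count, prob in self.sharing.items():
                if not 1 <= int(count) <= n_cell_types:
                    raise ValueError(f"sharing count {count} out of range")
                p[int(count) - 1] = prob
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("sharing probabilities must sum to 1")
        else:
            raise ValueError(f"unknown sharing profile {self.sharing!r}")
        return p


@dataclass
class CohortConfig:
    n_pcs: int = 10
    age_mean: float = 50.0
    age_sd: float = 10.0
    duration_mean: float = 10.0
    duration_sd: float = 4.0
    covariate_effect: float = 0.1  # standardized effect of age/gender/duration on phenotypes
    chunk: int = 20000
    max_draw: int = 5_000_000


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _block_profile(size: int, config: GenomeConfig) -> np.ndarray:
    """Unsigned within-block correlation template."""
    if config.ld_profile == "decaying":
        idx = np.arange(size)
        return config.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    mat = np.full((size, size), config.ld_rho)
    np.fill_diagonal(mat, 1.0)
    return mat


def _chol_psd(mat: np.ndarray, ridge: float = RIDGE) -> np.ndarray:
    """Cholesky with a documented ridge fallback for near-singular matrices."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(mat + ridge * np.eye(mat.shape[0]))


def generate_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Build a deterministic synthetic genome from a config and seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_variants

    gaps = config.spacing_min_bp + rng.geometric(
        1.0 / max(config.spacing_mean_bp - config.spacing_min_bp, 1), size=n
    )
    pos = 10_000 + np.cumsum(gaps)
    maf = rng.uniform(config.maf_min, config.maf_max, size=n)
    ea_idx = rng.integers(0, 4, size=n)
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:07d}" for i in range(n)],
            "chrom": config.chrom,
            "pos": pos.astype(np.int64),
            "effect_allele": _BASES[ea_idx],
            "other_allele": _BASES[oa_idx],
            "maf": maf,
        }
    )

    starts = np.arange(0, n, config.block_size)
    blocks = []
    signs_all = rng.choice([-1.0, 1.0], size=n)
    for s in starts:
        size = min(config.block_size, n - s)
        base = _block_profile(size, config)
        sgn = signs_all[s : s + size]
        blocks.append(base * np.outer(sgn, sgn))
    ld = BlockLDMatrix(starts, blocks)

    genes = _generate_genes(config, rng, variants, ld)
    return GenomeModel(variants, ld, genes)


def _generate_genes(
    config: GenomeConfig,
    rng: np.random.Generator,
    variants: pd.DataFrame,
    ld: BlockLDMatrix,
) -> list[Gene]:
    """One gene per LD block (cycling), anchored on a variant inside an exon.

    Exons are kept narrow around their anchor variant so that planted causal
    variants map to exactly one gene; this keeps recovery tests clean.
    """
    n = len(variants)
    pos = variants["pos"].to_numpy()
    gaps_left = np.diff(pos, prepend=pos[0] - 2000)
    gaps_right = np.diff(pos, append=pos[-1] + 2000)
    halfwidth = np.maximum(np.minimum(gaps_left, gaps_right) // 3, 1)

    genes: list[Gene] = []
    n_blocks = ld.n_blocks
    for g in range(config.n_genes):
        block = g % n_blocks
        mates = ld.blockmates(ld.block_starts[block])
        # anchor in the central third of the block so that exons and 2-kb
        # promoter windows stay inside the block's physical span
        lo_i = len(mates) // 3
        hi_i = max(lo_i + 1, len(mates) - len(mates) // 3)
        anchor = int(rng.choice(mates[lo_i:hi_i]))
        lo = int(pos[anchor] - halfwidth[anchor])
        hi = int(pos[anchor] + halfwidth[anchor] + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < config.coding_fraction else "other"
        exons = [(lo, hi)]
        isoforms = [_make_isoform(strand, exons)]
        if config.max_isoforms > 1 and rng.random() < 0.5:
            # second isoform: same exon plus a short downstream extension
            ext = int(rng.integers(50, 200))
            if strand == "+":
                exons2 = [(lo, hi), (hi + 10, hi + 10 + ext)]
            else:
                exons2 = [(lo - 10 - ext, lo - 10), (lo, hi)]
            isoforms.append(_make_isoform(strand, exons2))
        genes.append(Gene(f"GENE{g:05d}", variants["chrom"].iloc[0], strand, biotype, isoforms))
    return genes


def _make_isoform(strand: str, exons: list[tuple[int, int]]) -> Isoform:
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    return Isoform(tss=lo if strand == "+" else hi - 1, exons=exons)


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------


def make_truth(
    genome: GenomeModel,
    seed: int,
    *,
    n_causal_genes: int = 0,
    causal_beta: float = 0.05,
    n_causal_variants: int = 0,
    heritability: float = 0.0,
    prevalence: float = 0.00127,
    enriched_annotations: dict[str, float] | None = None,
    phenotype_effects: dict[str, float] | None = None,
    plant_threshold: float = 1e-5,
) -> SyntheticTruth:
    """Select causal genes/variants and record every planted parameter.

    Causal genes receive one causal variant inside an exon (their anchor).
    Free-standing causal variants are drawn at most one per LD block so the
    genetic variance is exactly the sum of squared standardized effects,
    which is then rescaled to the requested heritability.
    """
    rng = np.random.default_rng(seed)
    variants = genome.variants
    pos = variants["pos"].to_numpy()
    causal_variants: dict[str, float] = {}
    causal_genes: set[str] = set()

    if n_causal_genes > 0:
        coding = [g for g in genome.genes if g.biotype == "protein_coding"]
        if n_causal_genes > len(coding):
            raise ValueError("not enough protein-coding genes to plant")
        chosen = rng.choice(len(coding), size=n_causal_genes, replace=False)
        for gi in chosen:
            gene = coding[gi]
            exonic = _variants_in_exons(gene, pos)
            if exonic.size == 0:
                raise ValueError(f"gene {gene.gene_id} covers no variants")
            v = int(rng.choice(exonic))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            causal_variants[variants["variant_id"].iloc[v]] = sign * causal_beta
            causal_genes.add(gene.gene_id)

    if n_causal_variants > 0:
        used_blocks = {
            genome.ld.block_of(i)
            for i, vid in enumerate(variants["variant_id"])
            if vid in causal_variants
        }
        free_blocks = [b for b in range(genome.ld.n_blocks) if b not in used_blocks]
        if n_causal_variants > len(free_blocks):
            raise ValueError("not enough free LD blocks for causal variants")
        for b in rng.choice(free_blocks, size=n_causal_variants, replace=False):
            v = int(rng.choice(genome.ld.blockmates(genome.ld.block_starts[b])))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            causal_variants[variants["variant_id"].iloc[v]] = sign * causal_beta

    if heritability > 0:
        if not causal_variants:
            raise ValueError("heritability > 0 requires causal variants")
        idx = {v: i for i, v in enumerate(variants["variant_id"])}
        maf = variants["maf"].to_numpy()
        var_now = sum(
            (b * np.sqrt(2 * maf[idx[v]] * (1 - maf[idx[v]]))) ** 2
            for v, b in causal_variants.items()
        )
        scale = np.sqrt(heritability / var_now)
        causal_variants = {v: b * scale for v, b in causal_variants.items()}

    return SyntheticTruth(
        enriched_annotations=dict(enriched_annotations or {}),
        causal_genes=causal_genes,
        causal_variants=causal_variants,
        heritability=heritability,
        prevalence=prevalence,
        phenotype_effects=dict(phenotype_effects or {}),
        plant_threshold=plant_threshold,
    )


def _variants_in_exons(gene: Gene, pos: np.ndarray) -> np.ndarray:
    hit = np.zeros(pos.shape[0], dtype=bool)
    for iso in gene.isoforms:
        for s, e in iso.exons:
            hit |= (pos >= s) & (pos < e)
    return np.nonzero(hit)[0]


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def generate_gwas(
    genome: GenomeModel, truth: SyntheticTruth, n_eff: float, seed: int
) -> SummaryStats:
    """Draw per-block multivariate-normal Z-scores with LD-propagated means."""
    rng = np.random.default_rng(seed)
    variants = genome.variants
    maf = variants["maf"].to_numpy()
    beta = np.zeros(len(variants))
    idx = {v: i for i, v in enumerate(variants["variant_id"])}
    for v, b in truth.causal_variants.items():
        if v not in idx:
            raise ValueError(f"causal variant {v} not in genome")
        beta[idx[v]] = b

    nc = beta * np.sqrt(2 * maf * (1 - maf) * n_eff)  # per-variant non-centrality
    z = np.empty(len(variants))
    chol_cache: dict[tuple[int, int], np.ndarray] = {}
    for bi, (s, block) in enumerate(zip(genome.ld.block_starts, genome.ld.blocks)):
        size = block.shape[0]
        key = (size, bi if _needs_own_chol(block) else -size)
        if key not in chol_cache:
            chol_cache[key] = _chol_psd(np.abs(block))
        L = chol_cache[key]
        # with R = D_s |R| D_s the factor of R is D_s chol(|R|), so flipping
        # signs on the output of the unsigned factor gives the signed draw
        sgn = np.sign(block[0]).copy()
        sgn[0] = 1.0
        sgn[sgn == 0] = 1.0
        mean = block @ nc[s : s + size]
        eps = rng.standard_normal(size)
        z[s : s + size] = mean + sgn * (L @ eps)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_eff)
    p = 2 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = variants.copy()
    table["beta"] = z * se
    table["se"] = se
    table["p"] = p
    table["info"] = 1.0
    return SummaryStats(table, label=f"synthetic_gwas_neff{int(n_eff)}")


def _needs_own_chol(block: np.ndarray) -> bool:
    """Blocks differing only by sign conjugation share a Cholesky factor."""
    sgn = np.sign(block[0]).copy()
    sgn[sgn == 0] = 1.0
    return not np.allclose(np.abs(block), block * np.outer(sgn, sgn), atol=1e-12)


# ---------------------------------------------------------------------------
# annotations (peaks) and loops
# ---------------------------------------------------------------------------


def generate_annotations(
    genome: GenomeModel,
    config: AnnotationConfig,
    seed: int,
    truth: SyntheticTruth | None = None,
    stats: SummaryStats | None = None,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Per-cell-type peak sets with known sharing counts and planted enrichment.

    Two peak populations are produced:

    * background consensus units placed in inter-variant gaps, with a
      membership count drawn from the sharing profile;
    * variant-anchored peaks (only when ``stats`` is given): each cell type
      overlaps each variant independently with baseline probability p0, except
      that cell types named in ``truth.enriched_annotations`` get
      log-odds(p0) + planted log-OR for variants significant at
      ``truth.plant_threshold``, which plants an exact 2x2 enrichment.

    Returns the peak sets and a truth table (one row per peak unit with its
    member cell types and sharing count).
    """
    if config.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    chrom = genome.variants["chrom"].iloc[0]
    pos = genome.variants["pos"].to_numpy()
    cells = [f"cell{c}" for c in range(config.n_cell_types)]
    intervals: dict[str, list[tuple[str, int, int]]] = {c: [] for c in cells}
    truth_rows = []

    # background units: non-overlapping, variant-free placement
    if config.n_background_peaks > 0:
        width = config.background_width_bp
        probs = config.sharing_probs(config.n_cell_types)
        span_lo, span_hi = int(pos[0]) + 1, int(pos[-1])
        slot = width + 50
        n_slots = max((span_hi - span_lo) // slot, config.n_background_peaks)
        chosen = rng.choice(n_slots, size=config.n_background_peaks, replace=False)
        for u, slot_i in enumerate(np.sort(chosen)):
            start = span_lo + int(slot_i) * slot
            end = start + width
            # shrink unit away from any variant it would cover
            inside = (pos >= start) & (pos < end)
            if inside.any():
                start = int(pos[inside].max()) + 1
                if end - start < 10:
                    continue
            count = 1 + rng.choice(config.n_cell_types, p=probs)
            members = sorted(rng.choice(config.n_cell_types, size=count, replace=False))
            for m in members:
                intervals[cells[m]].append((chrom, start, end))
            truth_rows.append(
                (f"bg{u:05d}", chrom, start, end, ",".join(cells[m] for m in members), count)
            )

    # variant-anchored peaks with optional planted enrichment
    if stats is not None:
        gaps_left = np.diff(pos, prepend=pos[0] - 2000)
        gaps_right = np.diff(pos, append=pos[-1] + 2000)
        half = np.maximum(np.minimum(gaps_left, gaps_right) // 3, 1)
        p0 = config.variant_peak_rate
        y = (stats.p < (truth.plant_threshold if truth else 1e-5)).astype(float)
        member_mat = np.zeros((len(pos), len(cells)), dtype=bool)
        for ci, cell in enumerate(cells):
            log_or = (truth.enriched_annotations.get(cell, 0.0) if truth else 0.0)
            logit = np.log(p0 / (1 - p0)) + log_or * y
            prob = 1.0 / (1.0 + np.exp(-logit))
            ind = rng.random(len(pos)) < prob
            member_mat[:, ci] = ind
            for vi in np.nonzero(ind)[0]:
                intervals[cell].append(
                    (chrom, int(pos[vi] - half[vi]), int(pos[vi] + half[vi] + 1))
                )
        for vi in np.nonzero(member_mat.any(axis=1))[0]:
            members = [cells[ci] for ci in np.nonzero(member_mat[vi])[0]]
            truth_rows.append(
                (
                    f"var{vi:07d}",
                    chrom,
                    int(pos[vi] - half[vi]),
                    int(pos[vi] + half[vi] + 1),
                    ",".join(members),
                    len(members),
                )
            )

    peaksets = {
        c: PeakSet(c, pd.DataFrame(intervals[c], columns=["chrom", "start", "end"]))
        if intervals[c]
        else PeakSet(c, pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)}))
        for c in cells
    }
    truth_table = pd.DataFrame(
        truth_rows, columns=["unit_id", "chrom", "start", "end", "members", "count"]
    )
    return peaksets, truth_table


def generate_loops(
    genome: GenomeModel,
    seed: int,
    *,
    n_loops: int = 50,
    anchor_width: int = 1000,
    cell_type: str = "loops",
    target_genes: list[str] | None = None,
) -> InteractionSet:
    """Enhancer-promoter style loops: one anchor on a gene promoter, the
    partner anchor around a distal variant in another LD block."""
    rng = np.random.default_rng(seed)
    chrom = genome.variants["chrom"].iloc[0]
    pos = genome.variants["pos"].to_numpy()
    gene_pool = (
        [g for g in genome.genes if g.gene_id in set(target_genes)]
        if target_genes
        else genome.genes
    )
    if not gene_pool:
        raise ValueError("no genes available for loop generation")
    rows = []
    for _ in range(n_loops):
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        iso = gene.isoforms[0]
        a1 = (max(iso.tss - anchor_width // 2, 0), iso.tss + anchor_width // 2)
        v = int(rng.integers(len(pos)))
        a2 = (max(int(pos[v]) - anchor_width // 2, 0), int(pos[v]) + anchor_width // 2)
        rows.append((chrom, a1[0], a1[1], chrom, a2[0], a2[1], float(rng.random())))
    return InteractionSet(
        cell_type,
        pd.DataFrame(
            rows,
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"],
        ),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _draw_dosages(
    rng: np.random.Generator, n: int, genome: GenomeModel
) -> np.ndarray:
    """Gaussian-copula dosages: exact Binomial(2, MAF) marginals, block LD."""
    maf = genome.variants["maf"].to_numpy()
    thresh = sps.norm.ppf(1 - maf)
    out = np.empty((n, genome.n_variants), dtype=np.int8)
    chol_cache: dict[int, np.ndarray] = {}
    for bi, (s, block) in enumerate(zip(genome.ld.block_starts, genome.ld.blocks)):
        size = block.shape[0]
        key = bi if _needs_own_chol(block) else -size
        if key not in chol_cache:
            chol_cache[key] = _chol_psd(np.abs(block))
        L = chol_cache[key]
        sgn = np.sign(block[0]).copy()
        sgn[0] = 1.0
        sgn[sgn == 0] = 1.0
        eps = rng.standard_normal((n, 2, size))
        latent = sgn * (eps @ L.T)
        out[:, s : s + size] = (latent > thresh[s : s + size]).sum(axis=1)
    return out


def generate_cohort(
    genome: GenomeModel,
    truth: SyntheticTruth,
    seed: int,
    *,
    sampling: str = "population",
    n_individuals: int | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    config: CohortConfig | None = None,
) -> CohortData:
    """Liability-threshold cohort with planted heritability and phenotypes.

    ``sampling='population'`` draws ``n_individuals`` unconditionally;
    ``sampling='case_control'`` rejection-samples until ``n_cases`` cases and
    ``n_controls`` controls are collected (raising if the draw budget in
    ``config.max_draw`` is exhausted, which happens at tiny prevalence).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    K, h2 = truth.prevalence, truth.heritability
    liab_thresh = sps.norm.ppf(1 - K)

    maf = genome.variants["maf"].to_numpy()
    idx = {v: i for i, v in enumerate(genome.variants["variant_id"])}
    b_std = np.zeros(genome.n_variants)
    for v, b in truth.causal_variants.items():
        b_std[idx[v]] = b * np.sqrt(2 * maf[idx[v]] * (1 - maf[idx[v]]))

    def draw_chunk(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = _draw_dosages(rng, n, genome)
        zd = (d - 2 * maf) / np.sqrt(2 * maf * (1 - maf))
        g = zd @ b_std
        liab = g + np.sqrt(max(1 - h2, 0)) * rng.standard_normal(n)
        return d, g, liab

    if sampling == "population":
        if n_individuals is None:
            raise ValueError("population sampling requires n_individuals")
        dos, g, liab = draw_chunk(n_individuals)
        status = (liab > liab_thresh).astype(np.int8)
    elif sampling == "case_control":
        if n_cases is None or n_controls is None:
            raise ValueError("case_control sampling requires n_cases and n_controls")
        parts_d, parts_g, parts_s = [], [], []
        have_cases = have_controls = drawn = 0
        while have_cases < n_cases or have_controls < n_controls:
            if drawn >= config.max_draw:
                raise RuntimeError(
                    f"drew {drawn} individuals without reaching {n_cases} cases at "
                    f"K={K}; increase CohortConfig.max_draw or the prevalence"
                )
            chunk = min(config.chunk, config.max_draw - drawn)
            d, g, liab = draw_chunk(chunk)
            drawn += chunk
            case = liab > liab_thresh
            need_ca = n_cases - have_cases
            need_co = n_controls - have_controls
            ca_idx = np.nonzero(case)[0][:need_ca]
            co_idx = np.nonzero(~case)[0][:need_co]
            keep = np.concatenate([ca_idx, co_idx])
            parts_d.append(d[keep])
            parts_g.append(g[keep])
            parts_s.append(case[keep].astype(np.int8))
            have_cases += len(ca_idx)
            have_controls += len(co_idx)
        dos = np.concatenate(parts_d)
        g = np.concatenate(parts_g)
        status = np.concatenate(parts_s)
        perm = rng.permutation(len(status))
        dos, g, status = dos[perm], g[perm], status[perm]
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")

    n = len(status)
    age = rng.normal(config.age_mean, config.age_sd, n)
    gender = rng.integers(0, 2, n)
    duration = np.clip(rng.normal(config.duration_mean, config.duration_sd, n), 0.1, None)
    pcs = rng.standard_normal((n, config.n_pcs))
    covariates = pd.DataFrame({"age": age, "gender": gender, "duration": duration})
    for k in range(config.n_pcs):
        covariates[f"pc{k + 1}"] = pcs[:, k]

    score_std = g / np.sqrt(h2) if h2 > 0 else np.zeros(n)
    phenos = {}
    z_age = (age - config.age_mean) / config.age_sd
    z_dur = (duration - config.duration_mean) / config.duration_sd
    z_sex = 2.0 * gender - 1.0
    ce = config.covariate_effect
    for name, beta_p in truth.phenotype_effects.items():
        resid_var = 1.0 - beta_p**2 - 3 * ce**2
        if resid_var < 0:
            raise ValueError(f"phenotype {name}: planted effects exceed unit variance")
        phenos[name] = (
            beta_p * score_std
            + ce * (z_age + z_dur + z_sex)
            + np.sqrt(resid_var) * rng.standard_normal(n)
        )
    phenotypes = pd.DataFrame(phenos, index=range(n))

    dosages = pd.DataFrame(
        dos, columns=genome.variants["variant_id"].tolist(), index=range(n)
    )
    alleles = genome.variants[["variant_id", "effect_allele", "other_allele", "maf"]].copy()
    return CohortData(
        dosages=dosages,
        status=status,
        phenotypes=phenotypes,
        covariates=covariates,
        variant_alleles=alleles,
        true_score=score_std,
    )


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    obj = {
        "enriched_annotations": truth.enriched_annotations,
        "causal_genes": sorted(truth.causal_genes),
        "causal_variants": truth.causal_variants,
        "heritability": truth.heritability,
        "prevalence": truth.prevalence,
        "phenotype_effects": truth.phenotype_effects,
        "plant_threshold": truth.plant_threshold,
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    obj = json.loads(Path(path).read_text())
    return SyntheticTruth(
        enriched_annotations=obj["enriched_annotations"],
        causal_genes=set(obj["causal_genes"]),
        causal_variants=obj["causal_variants"],
        heritability=obj["heritability"],
        prevalence=obj["prevalence"],
        phenotype_effects=obj["phenotype_effects"],
        plant_threshold=obj["plant_threshold"],
    )
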