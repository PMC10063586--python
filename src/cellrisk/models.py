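"""Domain containers shared across the pipeline.

All genomic intervals are 0-based half-open. Variants are points (their bp
position). Gene models are isoform-resolved: each isoform carries its own
TSS and exon list, and promoter windows are defined per isoform downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import BlockLDMatrix

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p",
    "maf",
    "info",
]


@dataclass
class Isoform:
    """One transcript: strand-aware TSS plus exon intervals (half-open)."""

    tss: int
    exons: list[tuple[int, int]]

    def validate(self) -> None:
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"exon ({s},{e}) has non-positive length")


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    biotype: str  # 'protein_coding' or 'other'
    isoforms: list[Isoform]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for iso in self.isoforms:
            iso.validate()
            lo = min(s for s, _ in iso.exons)
            hi = max(e for _, e in iso.exons)
            # TSS sits at the 5' end of the transcript span
            if self.strand == "+" and iso.tss != lo:
                raise ValueError(f"{self.gene_id}: + strand TSS must be leftmost")
            if self.strand == "-" and iso.tss != hi - 1:
                raise ValueError(f"{self.gene_id}: - strand TSS must be rightmost")

    def span(self) -> tuple[int, int]:
        lo = min(s for iso in self.isoforms for s, _ in iso.exons)
        hi = max(e for iso in self.isoforms for _, e in iso.exons)
        return lo, hi


@dataclass
class PeakSet:
    """Intervals for one cell type / annotation source, 0-based half-open."""

    cell_type: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            bad = df.index[(df["end"] <= df["start"])][0]
            raise ValueError(f"interval {bad}: start must be < end")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "PeakSet":
        """Union of intervals; overlapping or bookended runs collapse."""
        out = []
        for chrom, grp in self.intervals.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s < cur_e:  # >=1 bp overlap joins; bookended stays separate
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return PeakSet(
            self.cell_type, pd.DataFrame(out, columns=["chrom", "start", "end"])
        )

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Half-open membership test for point positions, vectorized."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(pos.shape[0], dtype=bool)
        merged = self.merged().intervals
        for c, grp in merged.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            k = np.searchsorted(starts, pos[sel], side="right") - 1
            hit = (k >= 0) & (pos[sel] < ends[np.clip(k, 0, None)])
            out[sel] = hit
        return out


@dataclass
class InteractionSet:
    """Chromatin loops: two anchors per record, cis-only unless flagged."""

    cell_type: str
    loops: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2[,score]

    def __post_init__(self) -> None:
        cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        df = pd.DataFrame(self.loops)
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"loops missing column {c}")
        if "score" not in df.columns:
            df["score"] = np.nan
        for a in ("1", "2"):
            if (df[f"end{a}"] <= df[f"start{a}"]).any():
                raise ValueError(f"anchor{a}: start must be < end")
        self.loops = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.loops)


@dataclass
class SummaryStats:
    """Per-variant GWAS summary records, one row per variant."""

    table: pd.DataFrame
    label: str = "gwas"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if df["variant_id"].duplicated().any():
            dup = df["variant_id"][df["variant_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            raise ValueError(
                "p-values must lie in (0, 1]; replace p=0 with the smallest "
                "positive float before loading"
            )
        if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
            raise ValueError("MAF must lie in (0, 0.5]")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()

    def subset(self, mask_or_idx) -> "SummaryStats":
        return SummaryStats(self.table.iloc[mask_or_idx].copy(), self.label)


@dataclass
class GenomeModel:
    """Synthetic genome: variants + block LD + isoform-resolved gene models."""

    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, maf
    ld: BlockLDMatrix
    genes: list[Gene]

    def __post_init__(self) -> None:
        df = self.variants
        if self.ld.n_variants != len(df):
            raise ValueError("LD size does not match variant count")
        for _, grp in df.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        for g in self.genes:
            g.validate()

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class SyntheticTruth:
    """Planted parameters backing every downstream recovery test."""

    enriched_annotations: dict[str, float] = field(default_factory=dict)
    causal_genes: set[str] = field(default_factory=set)
    causal_variants: dict[str, float] = field(default_factory=dict)
    heritability: float = 0.0
    prevalence: float = 0.00127
    phenotype_effects: dict[str, float] = field(default_factory=dict)
    plant_threshold: float = 1e-5  # GWAS p cut defining "significant" for planting

    def __post_init__(self) -> None:
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must lie in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class CohortData:
    """Individual-level data: dosages, status, phenotypes, covariates."""

    dosages: pd.DataFrame  # individuals x variants, values in [0, 2]
    status: np.ndarray  # binary case/control
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    variant_alleles: pd.DataFrame | None = None  # variant_id, effect_allele, other_allele, maf
    true_score: np.ndarray | None = None  # planted standardized genetic score

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status)
        if not np.isin(self.status[~pd.isna(self.status)], [0, 1]).all():
            raise ValueError("status must be binary 0/1")
        d = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(d) < 0 or np.nanmax(d) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.dosages)


@dataclass
class AnnotationMatrix:
    """Variants x annotations binary indicators with annotation metadata."""

    variant_ids: np.ndarray
    annotation_ids: list[str]
    values: np.ndarray  # (n_variants, n_annotations) of {0,1}
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("annotation entries must be 0/1")
        if self.values.shape != (len(self.variant_ids), len(self.annotation_ids)):
            raise ValueError("annotation matrix shape mismatch")

    def column(self, annotation_id: str) -> np.ndarray:
        return self.values[:, self.annotation_ids.index(annotation_id)]


@dataclass
class EnrichmentResult:
    annotation_id: str
    threshold: float
    estimate: float | None  # log-odds of annotation overlap for significant variants
    se: float | None
    p: float | None
    n_pruned: int
    n_significant: int
    n_annotated: int
    testable: bool = True
    method: str = "logit"  # 'logit' or 'firth' fallback
    significant_after_correction: bool = False

    @property
    def odds_ratio(self) -> float | None:
        return None if self.estimate is None else float(np.exp(self.estimate))


class GeneSnpAnnotation:
    """Gene -> assigned variants, each tagged with its assignment routes."""

    ROUTES = ("exonic", "promoter", "interaction")

    def __init__(self, assignments: dict[str, dict[str, set[str]]] | None = None):
        self.assignments: dict[str, dict[str, set[str]]] = {}
        for gene, vmap in (assignments or {}).items():
            self.assignments[gene] = {v: set(r) for v, r in vmap.items()}

    def add(self, gene_id: str, variant_id: str, route: str) -> None:
        if route not in self.ROUTES:
            raise ValueError(f"unknown assignment route: {route}")
        self.assignments.setdefault(gene_id, {}).setdefault(variant_id, set()).add(
            route
        )

    def variants_for(self, gene_id: str) -> set[str]:
        return set(self.assignments.get(gene_id, {}))

    def all_variants(self) -> set[str]:
        out: set[str] = set()
        for vmap in self.assignments.values():
            out |= vmap.keys()
        return out

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.assignments.values())

    def merge(self, other: "GeneSnpAnnotation") -> "GeneSnpAnnotation":
        out = GeneSnpAnnotation(self.assignments)
        for gene, vmap in other.assignments.items():
            for v, routes in vmap.items():
                for r in routes:
                    out.add(gene, v, r)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, v, ",".join(sorted(r)))
            for g in sorted(self.assignments)
            for v, r in sorted(self.assignments[g].items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "variant_id", "routes"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSnpAnnotation":
        out = cls()
        for g, v, routes in df[["gene_id", "variant_id", "routes"]].itertuples(
            index=False
        ):
            for r in str(routes).split(","):
                out.add(g, v, r)
        return out


@dataclass
class GeneResult:
    gene_id: str
    biotype: str
    n_snps: int
    statistic: float
    p: float
    q: float | None = None
    risk_gene: bool = False
    independence_fallback: bool = False


@dataclass
class ScoreModel:
    """Selected variants + effect-allele weights defining one polygenic score."""

    variant_ids: np.ndarray
    weights: np.ndarray
    effect_alleles: np.ndarray
    p_threshold: float
    cell_type: str = "combined"
    snp_universe: str = "all_cell_snps"  # all_cell_snps | unique_cell_snps | combined
    mhc_excluded: bool = False

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        self.effect_alleles = np.asarray(self.effect_alleles)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")


@dataclass
class StratumOR:
    stratum: str
    lo_quantile: float
    hi_quantile: float
    n_cases: int
    n_controls: int
    odds_ratio: float
    se_log_or: float
    is_reference: bool = False


@dataclass
class CPRSResult:
    threshold: float
    r2_observed: float  # Nagelkerke incremental R2
    r2_liability: float  # prevalence-adjusted, liability scale
    auc: float
    p_association: float
    n: int
    strata: list[StratumOR] = field(default_factory=list)


@dataclass
class PhenotypeAssocResult:
    phenotype: str
    universe: str
    beta: float  # standardized-score, standardized-phenotype scale
    beta_raw: float
    se: float
    r2_incremental: float
    p: float
    n: int
    model: str = "linear"  # 'linear' or 'logistic'
    significant_after_correction: bool | None = None
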