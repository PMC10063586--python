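"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* Every internal coordinate is 0-based half-open. GTF (1-based inclusive) is
  converted on ingest and on write; BED/BEDPE pass through unchanged.
* Chromosome names are normalized to carry a ``chr`` prefix on ingest
  (configurable via ``normalize_chrom=False``).
* Floats are written with ``%.10g`` so that repeated runs with identical
  inputs produce byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import BlockLDMatrix
from .models import (
    Gene,
    GeneSnpAnnotation,
    InteractionSet,
    Isoform,
    PeakSet,
    SummaryStats,
    SUMMARY_COLUMNS,
)

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """File-format violation, carrying the offending line/record number."""


def _norm_chrom(c: str, normalize: bool) -> str:
    return c if not normalize or c.startswith("chr") else f"chr{c}"


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def read_bed(
    path: str | Path, cell_type: str | None = None, normalize_chrom: bool = True
) -> PeakSet:
    """BED3+ -> PeakSet; 0-based half-open intervals preserved exactly."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric coordinates"
                ) from exc
            if start >= end:
                raise ParseError(f"{path.name}:{lineno}: start >= end")
            rows.append((_norm_chrom(fields[0], normalize_chrom), start, end))
    name = cell_type if cell_type is not None else path.stem
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)}
    )
    return PeakSet(name, df)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    peaks.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(
    path: str | Path,
    cell_type: str | None = None,
    allow_trans: bool = False,
    normalize_chrom: bool = True,
) -> InteractionSet:
    """BEDPE -> InteractionSet; trans records rejected unless allowed."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path.name}:{lineno}: fewer than 6 columns")
            try:
                s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric coordinates"
                ) from exc
            c1 = _norm_chrom(f[0], normalize_chrom)
            c2 = _norm_chrom(f[3], normalize_chrom)
            if s1 >= e1 or s2 >= e2:
                raise ParseError(f"{path.name}:{lineno}: start >= end")
            if c1 != c2 and not allow_trans:
                raise ParseError(
                    f"{path.name}:{lineno}: trans interaction (pass allow_trans=True)"
                )
            score = float(f[6]) if len(f) > 6 and f[6] not in (".", "") else np.nan
            rows.append((c1, s1, e1, c2, s2, e2, score))
    name = cell_type if cell_type is not None else path.stem
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(
        {c: pd.Series(dtype=np.int64 if ("start" in c or "end" in c) else (float if c == "score" else str)) for c in cols}
    )
    return InteractionSet(name, df)


def write_bedpe(interactions: InteractionSet, path: str | Path) -> None:
    df = interactions.loops.copy()
    df["score"] = df["score"].map(
        lambda v: "." if pd.isna(v) else (FLOAT_FMT % v)
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models (GTF / BED12)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models(
    path: str | Path, dialect: str = "gtf", normalize_chrom: bool = True
) -> list[Gene]:
    """Parse gene models into isoform-resolved internal records.

    GTF coordinates (1-based inclusive) become 0-based half-open; the TSS of
    a minus-strand isoform is its largest transcript coordinate.
    """
    if dialect == "gtf":
        return _read_gtf(Path(path), normalize_chrom)
    if dialect == "bed12":
        return _read_bed12(Path(path), normalize_chrom)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gtf(path: Path, normalize_chrom: bool) -> list[Gene]:
    # gene_id/biotype -> transcript -> exon list
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tx -> (gene, chrom, strand, biotype)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path.name}:{lineno}: fewer than 9 columns")
            if f[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
            if not gene_id or not biotype:
                raise ParseError(
                    f"{path.name}:{lineno}: missing gene_id/gene_biotype attribute"
                )
            if not tx_id:
                raise ParseError(f"{path.name}:{lineno}: missing transcript_id")
            try:
                start, end = int(f[3]) - 1, int(f[4])  # GTF 1-based inclusive
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric coordinates") from exc
            chrom = _norm_chrom(f[0], normalize_chrom)
            tx_exons.setdefault(tx_id, []).append((start, end))
            tx_meta[tx_id] = (gene_id, chrom, f[6], biotype)

    genes: dict[str, Gene] = {}
    for tx_id, exons in tx_exons.items():
        gene_id, chrom, strand, biotype = tx_meta[tx_id]
        exons = sorted(exons)
        lo = min(s for s, _ in exons)
        hi = max(e for _, e in exons)
        iso = Isoform(tss=lo if strand == "+" else hi - 1, exons=exons)
        if gene_id not in genes:
            genes[gene_id] = Gene(gene_id, chrom, strand, _simple_biotype(biotype), [])
        genes[gene_id].isoforms.append(iso)
    out = list(genes.values())
    for g in out:
        g.validate()
    return out


def _simple_biotype(b: str) -> str:
    return "protein_coding" if b == "protein_coding" else "other"


def _read_bed12(path: Path, normalize_chrom: bool) -> list[Gene]:
    """BED12, one isoform per line; name field ``gene_id|biotype``."""
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path.name}:{lineno}: BED12 needs 12 columns")
            chrom = _norm_chrom(f[0], normalize_chrom)
            start, strand = int(f[1]), f[5]
            name_parts = f[3].split("|")
            gene_id = name_parts[0]
            biotype = name_parts[1] if len(name_parts) > 1 else "protein_coding"
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            lo = min(s for s, _ in exons)
            hi = max(e for _, e in exons)
            iso = Isoform(tss=lo if strand == "+" else hi - 1, exons=sorted(exons))
            if gene_id not in genes:
                genes[gene_id] = Gene(gene_id, chrom, strand, _simple_biotype(biotype), [])
            genes[gene_id].isoforms.append(iso)
    out = list(genes.values())
    for g in out:
        g.validate()
    return out


def write_gtf(genes: list[Gene], path: str | Path) -> None:
    """Write exon records (1-based inclusive) with gene/transcript attributes."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span()[0], g.gene_id)):
            for ti, iso in enumerate(g.isoforms):
                for s, e in iso.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.{ti}"; '
                        f'gene_biotype "{g.biotype}";'
                    )
                    fh.write(
                        f"{g.chrom}\tcellrisk\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# summary statistics / tables / dosages
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {c: c for c in SUMMARY_COLUMNS}


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    label: str | None = None,
) -> SummaryStats:
    """Tab-delimited summary statistics with a configurable column map.

    ``column_map`` maps internal names (see ``SUMMARY_COLUMNS``) to the file's
    column headers. p = 0 is rejected with advice rather than silently kept.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    df = pd.read_csv(path, sep="\t")
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required column(s) {missing}")
    out = pd.DataFrame({internal: df[src] for internal, src in cmap.items()})
    if (out["p"] == 0).any():
        bad = out.loc[out["p"] == 0, "variant_id"].iloc[0]
        raise ParseError(
            f"{path.name}: p = 0 at variant {bad}; replace exact zeros with the "
            "smallest positive float (5e-324) before loading"
        )
    return SummaryStats(out, label=label or path.stem)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.table[SUMMARY_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_table(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate TSV with a header row."""
    return pd.read_csv(Path(path), sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Dosage matrix (individuals x variants).

    ``.vcf`` files are parsed with a minimal VCF reader that takes the DS
    FORMAT field; anything else is read as a TSV whose first column is the
    sample id and whose remaining headers are variant ids.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf_ds(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df.astype(float)


def write_dosages_tsv(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, sep="\t", index=True, index_label="sample", float_format=FLOAT_FMT)


def _read_vcf_ds(path: Path) -> pd.DataFrame:
    samples: list[str] = []
    variant_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path.name}:{lineno}: missing sample columns")
            fmt = f[8].split(":")
            if "DS" not in fmt:
                raise ParseError(f"{path.name}:{lineno}: FORMAT lacks DS field")
            ds_i = fmt.index("DS")
            variant_ids.append(f[2])
            try:
                rows.append(
                    np.array(
                        [
                            np.nan if v.split(":")[ds_i] == "." else float(v.split(":")[ds_i])
                            for v in f[9:]
                        ]
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad DS value") from exc
    if not samples:
        raise ParseError(f"{path.name}: missing #CHROM header line")
    mat = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return pd.DataFrame(mat, index=samples, columns=variant_ids)


def write_vcf_ds(
    dosages: pd.DataFrame, variants: pd.DataFrame, path: str | Path
) -> None:
    """Minimal VCF with per-sample DS dosage field."""
    vmeta = variants.set_index("variant_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in dosages.index)
            + "\n"
        )
        for vid in dosages.columns:
            row = vmeta.loc[vid]
            vals = "\t".join(
                "." if pd.isna(v) else (FLOAT_FMT % v) for v in dosages[vid]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{vid}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tDS\t{vals}\n"
            )


# ---------------------------------------------------------------------------
# LD table / gene-SNP annotation
# ---------------------------------------------------------------------------


def write_ld(ld: BlockLDMatrix, variant_ids: np.ndarray, path: str | Path) -> None:
    """Within-block pairs (i < j) as a three-column TSV: id_a, id_b, r."""
    with open(path, "w") as fh:
        fh.write("variant_a\tvariant_b\tr\n")
        for s, block in zip(ld.block_starts, ld.blocks):
            size = block.shape[0]
            for i in range(size):
                for j in range(i + 1, size):
                    fh.write(
                        f"{variant_ids[s + i]}\t{variant_ids[s + j]}\t"
                        f"{FLOAT_FMT % block[i, j]}\n"
                    )


def read_ld(path: str | Path, variant_ids: np.ndarray) -> BlockLDMatrix:
    """Rebuild the block matrix from a pair table.

    Blocks are recovered as maximal contiguous index ranges connected by at
    least one recorded pair; pairs absent from the file are r = 0.
    """
    idx = {v: i for i, v in enumerate(variant_ids)}
    n = len(variant_ids)
    df = pd.read_csv(Path(path), sep="\t")
    ia = df["variant_a"].map(idx).to_numpy()
    ib = df["variant_b"].map(idx).to_numpy()
    if np.isnan(ia.astype(float)).any() or np.isnan(ib.astype(float)).any():
        raise ParseError("LD table names variants absent from the summary stats")
    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    # sweep to find contiguous connected ranges
    reach = np.arange(n)
    for a, b in zip(lo, hi):
        reach[a] = max(reach[a], b)
    starts, blocks = [], []
    i = 0
    while i < n:
        j = i
        end = reach[i]
        while j < end:
            j += 1
            end = max(end, reach[j])
        size = end - i + 1
        mat = np.eye(size)
        starts.append(i)
        i = end + 1
        blocks.append(mat)
    ld = BlockLDMatrix(np.array(starts), blocks)
    for a, b, r in zip(lo, hi, df["r"].to_numpy()):
        bi = ld.block_of(a)
        s = ld.block_starts[bi]
        ld.blocks[bi][a - s, b - s] = r
        ld.blocks[bi][b - s, a - s] = r
    return ld


def write_gene_snp_annotation(ann: GeneSnpAnnotation, path: str | Path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_snp_annotation(path: str | Path) -> GeneSnpAnnotation:
    return GeneSnpAnnotation.from_frame(pd.read_csv(Path(path), sep="\t"))
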