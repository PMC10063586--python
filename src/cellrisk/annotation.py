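"""Cell-type-specific peak derivation and per-variant annotation vectors.

Peaks from all cell types are merged into consensus units (>= 1 bp overlap
joins); a unit is cell-type-specific iff the number of cell types containing
it is at most ``max_sharing_fraction`` times the number of cell types, with an
inclusive comparison at exactly half.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ld import BlockLDMatrix
from .models import AnnotationMatrix, PeakSet, SummaryStats


def consensus_peaks(peaksets: list[PeakSet]) -> pd.DataFrame:
    """Merge all cell types' peaks into consensus units with membership counts.

    Returns one row per unit: chrom, start, end, members (comma-joined cell
    types), count.
    """
    frames = []
    for ps in peaksets:
        df = ps.intervals.copy()
        df["cell_type"] = ps.cell_type
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)
    if allp.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "members", "count"])
    rows = []
    for chrom, grp in allp.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cells = grp["cell_type"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        cur_members = {cells[0]}
        for s, e, c in zip(starts[1:], ends[1:], cells[1:]):
            if s < cur_e:
                cur_e = max(cur_e, e)
                cur_members.add(c)
            else:
                rows.append((chrom, cur_s, cur_e, cur_members))
                cur_s, cur_e, cur_members = s, e, {c}
        rows.append((chrom, cur_s, cur_e, cur_members))
    return pd.DataFrame(
        [
            (c, s, e, ",".join(sorted(m)), len(m))
            for c, s, e, m in rows
        ],
        columns=["chrom", "start", "end", "members", "count"],
    )


def derive_cell_specific_peaks(
    peaksets: list[PeakSet], max_sharing_fraction: float = 0.5
) -> dict[str, PeakSet]:
    """Cell-type-specific peaks: consensus units present in at most
    ``max_sharing_fraction`` of the cell types (inclusive at the boundary).

    Each qualifying unit is emitted into the specific set of every cell type
    that contains it.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least 2 cell types")
    n_cells = len(peaksets)
    units = consensus_peaks(peaksets)
    if units.empty:
        warnings.warn("all peak sets are empty; specific sets are empty")
    max_count = max_sharing_fraction * n_cells
    out: dict[str, list[tuple[str, int, int]]] = {ps.cell_type: [] for ps in peaksets}
    for chrom, start, end, members, count in units.itertuples(index=False):
        if count <= max_count:
            for cell in members.split(","):
                out[cell].append((chrom, start, end))
    result = {}
    for cell, rows in out.items():
        df = (
            pd.DataFrame(rows, columns=["chrom", "start", "end"])
            if rows
            else pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                }
            )
        )
        result[cell] = PeakSet(cell, df)
    return result


def annotate_variants(
    stats: SummaryStats,
    annotation: PeakSet,
    proxies: dict[str, set[str]] | None = None,
) -> np.ndarray:
    """0/1 overlap indicator per variant (half-open position-in-interval).

    With ``proxies`` (variant id -> ids of LD proxies, r2 above the caller's
    threshold), a variant is also annotated when any of its proxies overlaps.
    """
    direct = annotation.contains(stats.chrom, stats.pos).astype(np.int8)
    if not proxies:
        return direct
    pos_of = dict(zip(stats.variant_ids, zip(stats.chrom, stats.pos)))
    hit = dict(zip(stats.variant_ids, direct))
    out = direct.copy()
    for i, vid in enumerate(stats.variant_ids):
        if out[i]:
            continue
        prox = proxies.get(vid)
        if not prox:
            continue
        known = [p for p in prox if p in hit]
        if any(hit[p] for p in known):
            out[i] = 1
            continue
        unknown = [p for p in prox if p not in hit and p in pos_of]
        if unknown:
            chroms = np.array([pos_of[p][0] for p in unknown])
            poss = np.array([pos_of[p][1] for p in unknown])
            if annotation.contains(chroms, poss).any():
                out[i] = 1
    return out


def proxies_from_ld(
    stats: SummaryStats, ld: BlockLDMatrix, r2_min: float = 0.8
) -> dict[str, set[str]]:
    """variant id -> ids of other variants with r2 > r2_min."""
    ids = stats.variant_ids
    out: dict[str, set[str]] = {}
    for i, vid in enumerate(ids):
        nb = ld.neighbors(i, r2_min)
        if nb.size:
            out[vid] = {ids[j] for j in nb}
    return out


def count_ld_proxies(ld: BlockLDMatrix, threshold: float = 0.8) -> np.ndarray:
    """Per-variant number of LD proxies (distinct others with r2 > threshold)."""
    return ld.proxy_counts(threshold)


def build_annotation_matrix(
    stats: SummaryStats,
    annotations: dict[str, PeakSet],
    proxies: dict[str, set[str]] | None = None,
    meta: pd.DataFrame | None = None,
) -> AnnotationMatrix:
    """Stack per-annotation indicator vectors into a variants x annotations
    matrix with stable column order (sorted annotation ids)."""
    ids = sorted(annotations)
    cols = [annotate_variants(stats, annotations[a], proxies) for a in ids]
    values = np.column_stack(cols) if cols else np.zeros((len(stats), 0), dtype=np.int8)
    return AnnotationMatrix(stats.variant_ids, ids, values, meta)
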