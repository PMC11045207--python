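"""Midpoint-in-peak mapping and gene-level count aggregation.

A promoter/enhancer region is linked to a scATAC peak iff the region's
midpoint lies inside the peak (half-open test, strand-agnostic). Counts of
all distinct peaks linked to a gene are summed per cell, low-signal entries
are zeroed by a per-gene z-score filter, and the result is log2(x+1)
transformed before scoring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import (
    GeneCellMatrix,
    GeneRegionTable,
    GenomicInterval,
    PeakCountDataset,
    RegionPeakMap,
    ValidationError,
)

logger = logging.getLogger("stemscore")


def midpoint(interval: GenomicInterval) -> int:
    """Midpoint of an interval, floor division, in internal 0-based coords."""
    return (interval.start + interval.end) // 2


def build_peak_trees(peaks: list[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index peaks per chromosome for point queries.

    intervaltree uses the same half-open convention as the internal
    coordinates, so ``tree[pos]`` is exactly ``start <= pos < end``.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, peak in enumerate(peaks):
        trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end, idx)
    return trees


def map_regions_to_peaks(
    regions: GeneRegionTable, peaks: list[GenomicInterval]
) -> RegionPeakMap:
    """Link each gene region to every peak containing its midpoint.

    Overlapping peaks are all recorded; regions whose midpoint falls in no
    peak simply contribute no rows. Returns an empty map (with a warning)
    when nothing overlaps.
    """
    trees = build_peak_trees(peaks)
    rows: list[tuple[str, int, int]] = []
    for region_index, rec in enumerate(
        regions.df[["gene_id", "chrom", "start", "end"]].itertuples(index=False)
    ):
        tree = trees.get(str(rec.chrom))
        if tree is None:
            continue
        mid = (int(rec.start) + int(rec.end)) // 2
        for hit in tree[mid]:
            rows.append((rec.gene_id, region_index, hit.data))
    if not rows:
        logger.warning("no gene region midpoint falls inside any peak")
    df = pd.DataFrame(rows, columns=list(RegionPeakMap.COLUMNS))
    df = df.sort_values(["gene_id", "region_index", "peak_index"]).reset_index(drop=True)
    return RegionPeakMap(df)


def aggregate_gene_counts(
    region_peak_map: RegionPeakMap,
    dataset: PeakCountDataset,
    gene_set: list[str] | None = None,
) -> GeneCellMatrix:
    """Sum raw counts of each gene's mapped peaks, per cell (stage=raw).

    A peak reachable through several regions of the same gene is counted
    once. Genes in ``gene_set`` without any mapped peak get an all-zero row
    (with a warning); by default the genes present in the map are used.
    """
    if gene_set is None:
        gene_ids = sorted(region_peak_map.gene_ids)
    else:
        gene_ids = list(gene_set)
    counts = dataset.counts.tocsr()
    values = np.zeros((len(gene_ids), dataset.n_cells), dtype=float)
    grouped = region_peak_map.df.groupby("gene_id")["peak_index"]
    peak_sets = {g: sorted(set(int(p) for p in s)) for g, s in grouped}
    missing = [g for g in gene_ids if g not in peak_sets]
    if missing:
        logger.warning(
            "%d gene(s) have no mapped peaks and get all-zero rows: %s",
            len(missing),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    for i, gene in enumerate(gene_ids):
        idx = peak_sets.get(gene)
        if idx:
            values[i] = np.asarray(counts[idx].sum(axis=0)).ravel()
    return GeneCellMatrix(
        gene_ids=gene_ids, barcodes=list(dataset.barcodes), values=values, stage="raw"
    )


def zscore_filter(
    matrix: GeneCellMatrix, z_cutoff: float = -1.0, axis: str = "gene"
) -> GeneCellMatrix:
    """Zero out low-signal entries (stage raw -> filtered).

    With ``axis="gene"`` (default) each gene row is standardized across
    cells (mean/sd, sd with denominator n-1) and entries with z < z_cutoff
    become 0, so lowly accessible cells contribute nothing to a gene's
    score. Constant rows (sd = 0) pass through unchanged. ``axis="cell"``
    standardizes each cell across genes instead.
    """
    if matrix.stage != "raw":
        raise ValidationError(f"zscore_filter expects stage 'raw', got {matrix.stage!r}")
    values = matrix.values
    if axis == "gene":
        if matrix.n_cells < 2:
            raise ValidationError("z-score filtering needs at least 2 cells")
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
    elif axis == "cell":
        if matrix.n_genes < 2:
            raise ValidationError("z-score filtering per cell needs at least 2 genes")
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, ddof=1, keepdims=True)
    else:
        raise ValidationError(f"axis must be 'gene' or 'cell', got {axis!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mu) / sd, np.inf)
    out = np.where(z < z_cutoff, 0.0, values)
    n_zeroed = int((z < z_cutoff).sum())
    logger.info("z-score filter zeroed %d of %d entries", n_zeroed, values.size)
    return GeneCellMatrix(
        gene_ids=list(matrix.gene_ids),
        barcodes=list(matrix.barcodes),
        values=out,
        stage="filtered",
    )


def average_association(
    regions: GeneRegionTable, region_peak_map: RegionPeakMap
) -> pd.Series:
    """Mean gene-association score over each gene's mapped (region, peak) records.

    Defined only for genes with at least one mapped record; genes absent
    from the map are excluded with a warning. Returns a Series indexed by
    gene_id.
    """
    if not len(region_peak_map):
        logger.warning("empty region-peak map: no association powers computed")
        return pd.Series(dtype=float, name="association_power")
    merged = region_peak_map.df.merge(
        regions.df["association_score"],
        left_on="region_index",
        right_index=True,
        how="left",
    )
    power = merged.groupby("gene_id")["association_score"].mean()
    power.name = "association_power"
    unmapped = set(regions.df["gene_id"]) - set(power.index)
    if unmapped:
        logger.warning(
            "%d gene(s) have no mapped regions and no association power", len(unmapped)
        )
    return power


def log_transform(matrix: GeneCellMatrix) -> GeneCellMatrix:
    """Apply log2(x+1) (stage -> logged).

    Normally applied after :func:`zscore_filter`; a raw matrix is also
    accepted for pipelines that skip the filter (signature accessibility
    uses none).
    """
    if matrix.stage not in ("raw", "filtered"):
        raise ValidationError(
            f"log_transform expects stage 'raw' or 'filtered', got {matrix.stage!r}"
        )
    return GeneCellMatrix(
        gene_ids=list(matrix.gene_ids),
        barcodes=list(matrix.barcodes),
        values=np.log2(matrix.values + 1.0),
        stage="logged",
    )
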