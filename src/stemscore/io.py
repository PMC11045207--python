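"""Readers and writers for every external format the pipeline touches.

Supported formats: BED3 (+ ignored extra columns) for peaks, BED3+state for
GSC discriminating regions, plain-text barcodes (one per line), MatrixMarket
integer triplets for peak x cell counts, and TSV for gene regions, state
signatures, importance tables and score tables.

All readers normalise coordinates to the internal 0-based half-open
convention. Inputs exported from 1-based inclusive sources (typical of
GeneCards/GeneAlaCart-style tables) declare ``coord_convention=
"one_based_inclusive"`` and are shifted by ``start - 1`` with ``end``
unchanged, which yields the same half-open interval.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    GSC_STATES,
    GeneImportanceTable,
    GeneRegionTable,
    GenomicInterval,
    GscRegionTable,
    PeakCountDataset,
    StateSignatureTable,
    StemnessResult,
    ValidationError,
)

logger = logging.getLogger("stemscore")

COORD_CONVENTIONS = ("bed0", "one_based_inclusive")


def _to_internal(start: np.ndarray, end: np.ndarray, coord_convention: str):
    """Convert coordinate columns to 0-based half-open."""
    if coord_convention not in COORD_CONVENTIONS:
        raise ValidationError(
            f"coord_convention must be one of {COORD_CONVENTIONS}, got {coord_convention!r}"
        )
    if coord_convention == "one_based_inclusive":
        return start - 1, end
    return start, end


def _from_internal(start: np.ndarray, end: np.ndarray, coord_convention: str):
    if coord_convention == "one_based_inclusive":
        return start + 1, end
    return start, end


def read_bed_intervals(path, coord_convention: str = "bed0") -> list[GenomicInterval]:
    """Read a BED file as intervals; columns beyond the third (including any
    strand column) are read and discarded — overlap tests downstream are
    strand-agnostic."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: BED file needs at least 3 columns")
    start, end = _to_internal(
        df[1].to_numpy(dtype=np.int64), df[2].to_numpy(dtype=np.int64), coord_convention
    )
    try:
        return [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df[0], start, end)
        ]
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_bed_intervals(intervals, path, extra_columns: dict | None = None) -> None:
    data = {
        0: [iv.chrom for iv in intervals],
        1: [iv.start for iv in intervals],
        2: [iv.end for iv in intervals],
    }
    df = pd.DataFrame(data)
    if extra_columns:
        for i, (_, values) in enumerate(extra_columns.items(), start=3):
            df[i] = list(values)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_barcodes(path) -> list[str]:
    with open(path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise ValidationError(f"{path}: duplicate barcodes")
    return barcodes


def read_peak_count_bundle(
    peaks_path,
    barcodes_path,
    counts_path,
    coord_convention: str = "bed0",
    transpose: bool = False,
) -> PeakCountDataset:
    """Read the (peaks.bed, barcodes.txt, counts.mtx) triple of one sample.

    The MatrixMarket file is expected with rows = peaks and columns = cells
    (the GEO deposition orientation); pass ``transpose=True`` for the
    opposite layout. Dimension mismatches between the matrix header and the
    peak/barcode files are fatal and name the offending file.
    """
    peaks = read_bed_intervals(peaks_path, coord_convention)
    barcodes = read_barcodes(barcodes_path)
    counts = sp.csr_matrix(scipy.io.mmread(counts_path))
    if transpose:
        counts = counts.T.tocsr()
    n_rows, n_cols = counts.shape
    if n_rows != len(peaks):
        raise ValidationError(
            f"{counts_path}: matrix has {n_rows} rows but {peaks_path} has "
            f"{len(peaks)} peaks"
        )
    if n_cols != len(barcodes):
        raise ValidationError(
            f"{counts_path}: matrix has {n_cols} columns but {barcodes_path} has "
            f"{len(barcodes)} barcodes"
        )
    if counts.nnz and counts.data.min() < 0:
        raise ValidationError(f"{counts_path}: negative counts are not allowed")
    counts.data = np.asarray(np.round(counts.data), dtype=np.int64)
    return PeakCountDataset(peaks=peaks, barcodes=barcodes, counts=counts)


def write_peak_count_bundle(dataset: PeakCountDataset, out_dir) -> dict[str, Path]:
    """Write peaks.bed / barcodes.txt / counts.mtx into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out_dir / "peaks.bed",
        "barcodes": out_dir / "barcodes.txt",
        "counts": out_dir / "counts.mtx",
    }
    write_bed_intervals(dataset.peaks, paths["peaks"])
    paths["barcodes"].write_text("".join(b + "\n" for b in dataset.barcodes))
    scipy.io.mmwrite(paths["counts"], sp.coo_matrix(dataset.counts))
    return paths


def read_gene_regions(path, coord_convention: str = "bed0") -> GeneRegionTable:
    """Read the gene promoter/enhancer annotation TSV.

    Expected header: gene_id, chrom, start, end, element_type,
    association_score. Unknown element types, non-numeric or negative
    association scores, and duplicate rows are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GeneRegionTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    start, end = _to_internal(
        df["start"].to_numpy(dtype=np.int64),
        df["end"].to_numpy(dtype=np.int64),
        coord_convention,
    )
    df = df.assign(start=start, end=end)
    try:
        return GeneRegionTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_gene_regions(
    table: GeneRegionTable, path, coord_convention: str = "bed0"
) -> None:
    df = table.df.copy()
    start, end = _from_internal(
        df["start"].to_numpy(), df["end"].to_numpy(), coord_convention
    )
    df["start"], df["end"] = start, end
    df.to_csv(path, sep="\t", index=False)


def read_signatures(path) -> StateSignatureTable:
    df = pd.read_csv(path, sep="\t")
    try:
        return StateSignatureTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_signatures(table: StateSignatureTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_gsc_regions(path, coord_convention: str = "bed0") -> GscRegionTable:
    """Read GSC discriminating regions: BED3 plus a 4th state column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise ValidationError(
            f"{path}: expected BED3 + state column ({GSC_STATES})"
        )
    start, end = _to_internal(
        df[1].to_numpy(dtype=np.int64), df[2].to_numpy(dtype=np.int64), coord_convention
    )
    out = pd.DataFrame(
        {"chrom": df[0].astype(str), "start": start, "end": end, "gsc_state": df[3]}
    )
    try:
        return GscRegionTable(out)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_gsc_regions(table: GscRegionTable, path) -> None:
    table.df.to_csv(path, sep="\t", header=False, index=False)


def read_importance_table(path) -> GeneImportanceTable:
    df = pd.read_csv(path, sep="\t")
    n_reps = int(df.attrs.get("n_reps", df["vote_count"].max())) if len(df) else 0
    # n_reps/min_votes are persisted as columns so the table is self-describing
    if "n_reps" in df.columns and len(df):
        n_reps = int(df["n_reps"].iloc[0])
    min_votes = int(df["min_votes"].iloc[0]) if "min_votes" in df.columns and len(df) else 0
    return GeneImportanceTable(
        df.drop(columns=[c for c in ("n_reps", "min_votes") if c in df.columns]),
        n_reps=n_reps,
        min_votes=min_votes,
    )


def write_importance_table(table: GeneImportanceTable, path) -> None:
    df = table.df.copy()
    df["n_reps"] = table.n_reps
    df["min_votes"] = table.min_votes
    df.to_csv(path, sep="\t", index=False)


def write_scores(result: StemnessResult, path) -> None:
    """Write the per-cell score table (TSV).

    Columns: barcode, raw_score, norm_score, stemness_class and, when
    populated, neftel_state and gsc_state. Floats are written at
    shortest-round-trip precision, so a write/read cycle is lossless.
    """
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_scores(path) -> StemnessResult:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": str, "stemness_class": str},
        float_precision="round_trip",
    )
    return StemnessResult(
        barcodes=list(df["barcode"]) if len(df) else [],
        raw_score=df["raw_score"].to_numpy() if len(df) else np.empty(0),
        norm_score=df["norm_score"].to_numpy() if len(df) else np.empty(0),
        stemness_class=df["stemness_class"].to_numpy() if len(df) else np.empty(0, object),
        neftel_state=df["neftel_state"].to_numpy() if "neftel_state" in df.columns else None,
        gsc_state=df["gsc_state"].to_numpy() if "gsc_state" in df.columns else None,
    )
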