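"""Core in-memory containers shared across the pipeline.

All genomic coordinates held by these containers are 0-based, half-open
(BED convention). Readers in :mod:`stemscore.io` convert other conventions
at the boundary, so overlap arithmetic inside the package never has to
reason about off-by-one shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when an input file or container violates a declared invariant."""


ELEMENT_TYPES = ("promoter", "enhancer")
GSC_STATES = ("constructive", "reactive", "invasive")
STAGES = ("raw", "filtered", "logged")
UNASSIGNED = "unassigned"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        """Half-open containment test: ``start <= position < end``."""
        return self.start <= position < self.end


@dataclass
class PeakCountDataset:
    """A single-sample scATAC-seq bundle: peaks, barcodes and raw counts.

    ``counts`` is a sparse (n_peaks x n_cells) matrix of non-negative
    integer read counts, rows aligned with ``peaks`` and columns with
    ``barcodes``.
    """

    peaks: list[GenomicInterval]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_peaks, n_cells = self.counts.shape
        if n_peaks != len(self.peaks):
            raise ValidationError(
                f"counts has {n_peaks} rows but {len(self.peaks)} peaks were given"
            )
        if n_cells != len(self.barcodes):
            raise ValidationError(
                f"counts has {n_cells} columns but {len(self.barcodes)} barcodes were given"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("cell barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


def _check_interval_columns(df: pd.DataFrame, context: str) -> None:
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValidationError(
            f"{context}: {len(bad)} row(s) with end <= start or negative start "
            f"(first offending row index {bad.index[0]})"
        )


@dataclass
class GeneRegionTable:
    """Per-gene promoter/enhancer intervals with gene-association scores.

    Backed by a DataFrame with columns ``gene_id, chrom, start, end,
    element_type, association_score``. The association score quantifies the
    strength of the functional gene/element link (GeneHancer-style) and is
    averaged per gene downstream.
    """

    df: pd.DataFrame

    COLUMNS = ("gene_id", "chrom", "start", "end", "element_type", "association_score")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"gene region table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        bad_type = ~df["element_type"].isin(ELEMENT_TYPES)
        if bad_type.any():
            values = sorted(df.loc[bad_type, "element_type"].unique())
            raise ValidationError(
                f"element_type must be one of {ELEMENT_TYPES}, got {values}"
            )
        score = pd.to_numeric(df["association_score"], errors="coerce")
        if score.isna().any():
            row = int(df.index[score.isna()][0])
            raise ValidationError(f"non-numeric association_score at row {row}")
        if (score < 0).any():
            row = int(df.index[score < 0][0])
            raise ValidationError(f"negative association_score at row {row}")
        if not np.isfinite(score).all():
            row = int(df.index[~np.isfinite(score)][0])
            raise ValidationError(f"non-finite association_score at row {row}")
        df["association_score"] = score.astype(float)
        _check_interval_columns(df, "gene region table")
        key_cols = ["gene_id", "chrom", "start", "end", "element_type"]
        dup = df.duplicated(subset=key_cols, keep=False)
        if dup.any():
            dupes = df.loc[dup, key_cols].drop_duplicates()
            raise ValidationError(
                f"duplicate (gene, interval, element_type) rows:\n{dupes.to_string(index=False)}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.df["gene_id"]))

    def interval(self, row_index: int) -> GenomicInterval:
        row = self.df.iloc[row_index]
        return GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))

    def subset(self, gene_ids=None, element_types=None) -> "GeneRegionTable":
        df = self.df
        if gene_ids is not None:
            df = df[df["gene_id"].isin(set(gene_ids))]
        if element_types is not None:
            df = df[df["element_type"].isin(set(element_types))]
        return GeneRegionTable(df.reset_index(drop=True))


@dataclass
class StateSignatureTable:
    """(state, gene_id) membership rows for cell-state marker signatures."""

    df: pd.DataFrame

    COLUMNS = ("state", "gene_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"signature table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        if df.duplicated(subset=["state", "gene_id"]).any():
            raise ValidationError("duplicate (state, gene_id) rows in signature table")
        self.df = df

    @property
    def states(self) -> list[str]:
        return list(pd.unique(self.df["state"]))

    def genes_for(self, state: str) -> list[str]:
        return list(self.df.loc[self.df["state"] == state, "gene_id"])


@dataclass
class GscRegionTable:
    """Bulk-ATAC discriminating regions, one GSC functional state per region."""

    df: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "gsc_state")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"GSC region table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        bad = ~df["gsc_state"].isin(GSC_STATES)
        if bad.any():
            values = sorted(df.loc[bad, "gsc_state"].unique())
            raise ValidationError(f"gsc_state must be one of {GSC_STATES}, got {values}")
        _check_interval_columns(df, "GSC region table")
        self.df = df

    @property
    def states(self) -> list[str]:
        return [s for s in GSC_STATES if s in set(self.df["gsc_state"])]


@dataclass
class GeneCellMatrix:
    """Gene x cell accessibility matrix with an explicit processing stage.

    Stages move strictly forward: ``raw`` (aggregated counts) -> ``filtered``
    (low-signal entries zeroed) -> ``logged`` (log2(x+1)). The z-score filter
    may be skipped, in which case ``raw`` transforms directly to ``logged``.
    """

    gene_ids: list[str]
    barcodes: list[str]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.barcodes)} cells)"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("gene-cell matrix values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.barcodes)


@dataclass
class RegionPeakMap:
    """Links gene regions to the scATAC peaks containing their midpoints.

    Rows are (gene_id, region_index, peak_index) where ``region_index``
    refers to rows of the source :class:`GeneRegionTable` and ``peak_index``
    to the peak order of the :class:`PeakCountDataset`.
    """

    df: pd.DataFrame

    COLUMNS = ("gene_id", "region_index", "peak_index")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"region-peak map missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.df["gene_id"]))

    def peaks_for_gene(self, gene_id: str) -> list[int]:
        """Distinct peak indices mapped to a gene (each counted once)."""
        sub = self.df.loc[self.df["gene_id"] == gene_id, "peak_index"]
        return sorted(set(int(p) for p in sub))


@dataclass
class GeneImportanceTable:
    """Per-learner vote counts and importances from the consensus protocol."""

    df: pd.DataFrame
    n_reps: int
    min_votes: int

    COLUMNS = ("gene_id", "learner", "vote_count", "mean_importance", "selected")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"importance table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        if (df["vote_count"] > self.n_reps).any():
            raise ValidationError("vote_count exceeds number of repetitions")
        expect = df["vote_count"] >= self.min_votes
        if not (df["selected"] == expect).all():
            raise ValidationError("selected flag inconsistent with vote_count/min_votes")
        self.df = df

    def selected_genes(self) -> list[str]:
        return sorted(self.df.loc[self.df["selected"], "gene_id"])


@dataclass
class StemnessResult:
    """Per-cell stemness scores, classes and optional state labels."""

    barcodes: list[str]
    raw_score: np.ndarray
    norm_score: np.ndarray
    stemness_class: np.ndarray
    neftel_state: np.ndarray | None = None
    gsc_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        self.norm_score = np.asarray(self.norm_score, dtype=float)
        self.stemness_class = np.asarray(self.stemness_class, dtype=object)
        for name in ("raw_score", "norm_score", "stemness_class"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match barcodes")
        if self.norm_score.size and (
            self.norm_score.min() < 0 or self.norm_score.max() > 1
        ):
            raise ValidationError("norm_score must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "barcode": self.barcodes,
            "raw_score": self.raw_score,
            "norm_score": self.norm_score,
            "stemness_class": self.stemness_class,
        }
        if self.neftel_state is not None:
            data["neftel_state"] = self.neftel_state
        if self.gsc_state is not None:
            data["gsc_state"] = self.gsc_state
        return pd.DataFrame(data)


@dataclass
class ClusterResult:
    """Hierarchical clustering of cells cut at k clusters (labels 1..k)."""

    cluster_id: np.ndarray
    k: int
    linkage_method: str
    distance_metric: str

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        if self.cluster_id.size and not (
            1 <= self.cluster_id.min() and self.cluster_id.max() <= self.k
        ):
            raise ValidationError("cluster ids must lie in 1..k")


@dataclass
class GroundTruth:
    """Bookkeeping of the planted structure in a synthetic dataset."""

    informative_gene_ids: set[str] = field(default_factory=set)
    stem_cell_barcodes: set[str] = field(default_factory=set)
    true_state_per_cell: dict[str, str] = field(default_factory=dict)
    true_gsc_state_per_cell: dict[str, str] = field(default_factory=dict)
    informative_gene_states: dict[str, str] = field(default_factory=dict)
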