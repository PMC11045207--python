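"""Cell-state assignment from signature accessibility and bulk-ATAC regions.

Two labelings are produced:

* Neftel-style states (NPC-like 1/2, OPC-like, AC-like, MES-like 1/2 in the
  original vocabulary; any state names are accepted): per state, cells are
  hierarchically clustered on the logged accessibility of that state's
  signature-gene promoters, and the cluster with the highest mean
  accessibility is flagged as the state's population.
* GSC functional states (constructive / reactive / invasive): cells passing
  the stemness cutoff are assigned to the state whose discriminating
  regions capture, on average per region, the most reads.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from intervaltree import IntervalTree
from scipy.spatial.distance import pdist

from .containers import (
    ClusterResult,
    GeneCellMatrix,
    GeneRegionTable,
    GscRegionTable,
    PeakCountDataset,
    StateSignatureTable,
    StemnessResult,
    UNASSIGNED,
    ValidationError,
)
from .mapping import aggregate_gene_counts, log_transform, map_regions_to_peaks, midpoint

logger = logging.getLogger("stemscore")

GSC_SIGNAL_MODES = ("mean", "sum", "length_normalized")


def signature_accessibility(
    signatures: StateSignatureTable,
    regions: GeneRegionTable,
    dataset: PeakCountDataset,
    state: str,
    include_enhancers: bool = False,
) -> GeneCellMatrix:
    """Logged accessibility of one state's signature genes (no z-filter).

    Restricts the annotation to the state's genes — promoters only by
    default — then reuses the midpoint-in-peak mapping, per-gene
    aggregation and log2(x+1) transform.
    """
    if state not in set(signatures.df["state"]):
        raise ValidationError(f"state {state!r} not present in signature table")
    genes = signatures.genes_for(state)
    element_types = ("promoter", "enhancer") if include_enhancers else ("promoter",)
    sub = regions.subset(gene_ids=genes, element_types=element_types)
    rpmap = map_regions_to_peaks(sub, dataset.peaks) if len(sub) else None
    if rpmap is None or not len(rpmap):
        raise ValidationError(
            f"state {state!r}: none of its signature genes map to any peak "
            f"(genes: {sorted(genes)})"
        )
    mapped = set(rpmap.gene_ids)
    raw = aggregate_gene_counts(rpmap, dataset, gene_set=sorted(mapped))
    return log_transform(raw)


def cluster_cells(
    matrix: GeneCellMatrix,
    k: int,
    linkage_method: str = "ward",
    distance_metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of cells (matrix columns) cut at k clusters."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > matrix.n_cells:
        raise ValidationError(f"k={k} exceeds the number of cells ({matrix.n_cells})")
    X = matrix.values.T  # cells x genes
    dist = pdist(X, metric=distance_metric)
    Z = sch.linkage(dist, method=linkage_method)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        cluster_id=labels, k=k, linkage_method=linkage_method, distance_metric=distance_metric
    )


def assign_state_cluster(clusters: ClusterResult, matrix: GeneCellMatrix) -> np.ndarray:
    """Flag the cells of the highest-mean-accessibility cluster.

    The cluster mean is taken over all signature genes and member cells;
    ties go to the smaller cluster id. Returns a boolean membership mask
    over cells.
    """
    if len(clusters.cluster_id) != matrix.n_cells:
        raise ValidationError("cluster labels and matrix cells are misaligned")
    best_id, best_mean = None, -np.inf
    for cid in range(1, clusters.k + 1):
        members = clusters.cluster_id == cid
        if not members.any():
            continue
        mean = float(matrix.values[:, members].mean())
        if mean > best_mean:  # strict: ties keep the smaller cluster id
            best_id, best_mean = cid, mean
    return clusters.cluster_id == best_id


def label_neftel_states(
    signatures: StateSignatureTable,
    regions: GeneRegionTable,
    dataset: PeakCountDataset,
    k: int,
    linkage_method: str = "ward",
    distance_metric: str = "euclidean",
    include_enhancers: bool = False,
) -> np.ndarray:
    """Assign each cell one signature state (or 'unassigned').

    Each state is processed independently (signature matrix -> cluster ->
    flag the top cluster). A cell flagged by several states takes the state
    with the larger per-cell mean signature accessibility.
    """
    n = dataset.n_cells
    best_state = np.full(n, UNASSIGNED, dtype=object)
    best_value = np.full(n, -np.inf)
    for state in signatures.states:
        matrix = signature_accessibility(
            signatures, regions, dataset, state, include_enhancers=include_enhancers
        )
        clusters = cluster_cells(matrix, k, linkage_method, distance_metric)
        members = assign_state_cluster(clusters, matrix)
        per_cell_mean = matrix.values.mean(axis=0)
        take = members & (per_cell_mean > best_value)
        best_state[take] = state
        best_value[take] = per_cell_mean[take]
    n_unassigned = int((best_state == UNASSIGNED).sum())
    logger.info(
        "state labeling: %d/%d cells assigned (%d unassigned)",
        n - n_unassigned,
        n,
        n_unassigned,
    )
    return best_state


def _peak_state_membership(
    dataset: PeakCountDataset, gsc_regions: GscRegionTable
) -> dict[str, np.ndarray]:
    """Peak indices whose midpoints fall inside each state's regions."""
    trees: dict[str, IntervalTree] = {}
    for rec in gsc_regions.df.itertuples(index=False):
        key = (rec.gsc_state, str(rec.chrom))
        trees.setdefault(key, IntervalTree()).addi(int(rec.start), int(rec.end))
    membership: dict[str, list[int]] = {s: [] for s in gsc_regions.states}
    for idx, peak in enumerate(dataset.peaks):
        mid = midpoint(peak)
        for state in membership:
            tree = trees.get((state, peak.chrom))
            if tree is not None and tree[mid]:
                membership[state].append(idx)
    return {s: np.asarray(v, dtype=int) for s, v in membership.items()}


def assign_gsc_state(
    dataset: PeakCountDataset,
    gsc_regions: GscRegionTable,
    stemness: StemnessResult,
    cutoff: float = 0.5,
    signal_mode: str = "mean",
) -> np.ndarray:
    """Assign high-stemness cells to a GSC functional state.

    Cells with normalized stemness below the cutoff stay unassigned. For
    the rest, the per-state signal is the total count in peaks whose
    midpoint lies in any of the state's discriminating regions, divided by
    the state's region count (``signal_mode="mean"``, default); ``"sum"``
    skips the division and ``"length_normalized"`` divides by the state's
    total region length in bp. The cell takes the argmax state; exact ties
    stay unassigned with a warning.
    """
    if signal_mode not in GSC_SIGNAL_MODES:
        raise ValidationError(
            f"signal_mode must be one of {GSC_SIGNAL_MODES}, got {signal_mode!r}"
        )
    if list(stemness.barcodes) != list(dataset.barcodes):
        raise ValidationError("stemness result and dataset barcodes are misaligned")
    states = gsc_regions.states
    if not states:
        raise ValidationError("GSC region table is empty")
    membership = _peak_state_membership(dataset, gsc_regions)
    counts = dataset.counts.tocsr()
    signals = np.zeros((len(states), dataset.n_cells))
    for i, state in enumerate(states):
        idx = membership[state]
        total = (
            np.asarray(counts[idx].sum(axis=0)).ravel()
            if len(idx)
            else np.zeros(dataset.n_cells)
        )
        sub = gsc_regions.df[gsc_regions.df["gsc_state"] == state]
        if signal_mode == "mean":
            denom = float(len(sub))
        elif signal_mode == "length_normalized":
            denom = float((sub["end"] - sub["start"]).sum())
        else:
            denom = 1.0
        signals[i] = total / denom
    assigned = np.full(dataset.n_cells, UNASSIGNED, dtype=object)
    passing = np.asarray(stemness.norm_score) >= cutoff
    best = signals.argmax(axis=0)
    top = signals.max(axis=0)
    n_ties = 0
    for c in np.flatnonzero(passing):
        if (signals[:, c] == top[c]).sum() > 1:
            n_ties += 1
            continue
        assigned[c] = states[best[c]]
    if n_ties:
        logger.warning("%d cell(s) left unassigned due to tied GSC signals", n_ties)
    return assigned


def summarize_groups(
    stemness: StemnessResult,
    neftel_state: np.ndarray | None = None,
    gsc_state: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (gsc_state x neftel_state) summary of normalized stemness scores.

    Groups over the cross product of the observed state vocabularies;
    empty groups appear with n=0. Columns: gsc_state, neftel_state, n,
    mean, median, min, max.
    """
    neftel = (
        np.asarray(neftel_state, dtype=object)
        if neftel_state is not None
        else (stemness.neftel_state if stemness.neftel_state is not None else None)
    )
    gsc = (
        np.asarray(gsc_state, dtype=object)
        if gsc_state is not None
        else (stemness.gsc_state if stemness.gsc_state is not None else None)
    )
    n = len(stemness.barcodes)
    if neftel is None:
        neftel = np.full(n, UNASSIGNED, dtype=object)
    if gsc is None:
        gsc = np.full(n, UNASSIGNED, dtype=object)
    norm = np.asarray(stemness.norm_score)
    rows = []
    for g in sorted(set(gsc)):
        for s in sorted(set(neftel)):
            mask = (gsc == g) & (neftel == s)
            vals = norm[mask]
            rows.append(
                {
                    "gsc_state": g,
                    "neftel_state": s,
                    "n": int(mask.sum()),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                    "min": float(vals.min()) if len(vals) else np.nan,
                    "max": float(vals.max()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)
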