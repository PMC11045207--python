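"""Weighted chromatin stemness score.

The score of a cell is the weighted sum over the consensus gene list G of
its log-transformed aggregated accessibility:

    score(c) = sum_{i in G} w_i * x_i(c)

where w_i combines the gene's machine-learning importance with its mean
gene-association power, and scores are min-max normalized to [0, 1] per
sample. Cells above the 0.5 cutoff are called high-stemness.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GeneCellMatrix, StemnessResult, ValidationError

logger = logging.getLogger("stemscore")

WEIGHT_MODES = ("rescale", "center")


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError(
            f"cannot standardize {name}: zero variance across the gene set "
            "(all values identical, weights undefined)"
        )
    return (x - x.mean()) / sd


def _rescale01(x: np.ndarray, name: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("%s has zero range; all genes weighted equally", name)
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def compute_weights(
    importance: Mapping[str, float],
    association: Mapping[str, float],
    gene_set: list[str],
    mode: str = "rescale",
) -> pd.DataFrame:
    """Combine importance and association power into per-gene weights.

    Each factor is normalized across ``gene_set`` and the weight is their
    product. ``mode="rescale"`` (default) maps each factor to [0, 1] by
    min-max rescaling, keeping every weight non-negative so higher
    accessibility at a consensus gene can only raise the score.
    ``mode="center"`` z-standardizes each factor (mean 0, sd with
    denominator n-1) instead; centered factors can be negative and their
    product can flip sign, which is logged.

    Returns a DataFrame indexed by gene_id with columns importance_std,
    association_std, weight.
    """
    if mode not in WEIGHT_MODES:
        raise ValidationError(f"mode must be one of {WEIGHT_MODES}, got {mode!r}")
    genes = list(gene_set)
    if len(genes) < 2:
        raise ValidationError("weight computation needs at least 2 genes")
    missing_imp = [g for g in genes if g not in importance]
    missing_assoc = [g for g in genes if g not in association]
    if missing_imp or missing_assoc:
        raise ValidationError(
            "genes missing from importance map: "
            f"{missing_imp}; from association map: {missing_assoc}"
        )
    imp = np.array([float(importance[g]) for g in genes])
    assoc = np.array([float(association[g]) for g in genes])
    if mode == "center":
        imp_n = _standardize(imp, "gene importance")
        assoc_n = _standardize(assoc, "association power")
    else:
        imp_n = _rescale01(imp, "gene importance")
        assoc_n = _rescale01(assoc, "association power")
    weight = imp_n * assoc_n
    n_negative = int((weight < 0).sum())
    if n_negative:
        logger.info(
            "%d of %d gene weights are negative (double-negation sign flips possible)",
            n_negative,
            len(genes),
        )
    return pd.DataFrame(
        {"importance_std": imp_n, "association_std": assoc_n, "weight": weight},
        index=pd.Index(genes, name="gene_id"),
    )


def raw_scores(weights: pd.DataFrame, matrix: GeneCellMatrix) -> np.ndarray:
    """Per-cell weighted sum of logged accessibility over the gene list."""
    if matrix.stage != "logged":
        raise ValidationError(
            f"raw_scores expects a logged matrix, got stage {matrix.stage!r}"
        )
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in weights.index if g not in gene_index]
    if missing:
        raise ValidationError(
            f"matrix is missing rows for weighted genes: {sorted(missing)}"
        )
    rows = [gene_index[g] for g in weights.index]
    w = weights["weight"].to_numpy()
    return w @ matrix.values[rows]


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Scale raw scores to [0, 1]; a constant vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("cannot normalize an empty score vector")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("all raw scores equal (%g); normalized scores set to 0", lo)
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def classify_stemness(norm: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Label cells 'high' iff normalized score exceeds the cutoff.

    Cells at exactly the cutoff are 'low' (strict inequality).
    """
    norm = np.asarray(norm, dtype=float)
    if norm.size and (norm.min() < 0 or norm.max() > 1):
        raise ValidationError("normalized scores must lie in [0, 1]")
    return np.where(norm > cutoff, "high", "low").astype(object)


def score_cells(
    weights: pd.DataFrame,
    matrix: GeneCellMatrix,
    cutoff: float = 0.5,
) -> StemnessResult:
    """Convenience wrapper: raw score -> min-max normalize -> classify."""
    raw = raw_scores(weights, matrix)
    norm = minmax_normalize(raw)
    return StemnessResult(
        barcodes=list(matrix.barcodes),
        raw_score=raw,
        norm_score=norm,
        stemness_class=classify_stemness(norm, cutoff=cutoff),
    )
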