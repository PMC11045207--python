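"""Consensus gene selection from labeled scRNA-seq with tree ensembles.

Three multiclass learners — random forest (rf), gradient boosting (gb) and
extreme gradient boosting (xgb) — are each fit on repeated stratified
70/30 splits. Per repetition the top-k genes by the learner's native
(impurity/gain) feature importance are recorded; genes appearing in at
least ``min_votes`` of ``n_reps`` repetitions form that learner's selected
set, and the cross-learner consensus (default: intersection) is the gene
list used for stemness scoring.

Presets:
    rf  — 500 trees, sqrt(n_genes) features per split
    gb  — 2500 trees, learning rate 0.001, depth 5, >=5 obs per leaf
          (backed by LightGBM)
    xgb — 2500 rounds, depth 15, eta 0.001, column subsample 0.5

Repetition r derives its seed as ``seed + r`` for both the split and the
learner, so any single repetition can be replayed in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import GeneImportanceTable, ValidationError

logger = logging.getLogger("stemscore")

LEARNER_NAMES = ("rf", "gb", "xgb")

PRESETS: dict[str, dict] = {
    "rf": {"n_estimators": 500, "max_features": "sqrt"},
    "gb": {
        "n_estimators": 2500,
        "learning_rate": 0.001,
        "max_depth": 5,
        "min_child_samples": 5,
    },
    "xgb": {
        "n_estimators": 2500,
        "max_depth": 15,
        "learning_rate": 0.001,
        "colsample_bytree": 0.5,
    },
}


@dataclass(frozen=True)
class LearnerSpec:
    """A named tree-ensemble learner with optional hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ValidationError(
                f"learner must be one of {LEARNER_NAMES}, got {self.name!r}"
            )

    def resolved(self) -> dict:
        params = dict(PRESETS[self.name])
        params.update(self.hyperparameters)
        return params


def _make_estimator(spec: LearnerSpec, seed: int):
    params = spec.resolved()
    if spec.name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if spec.name == "gb":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, importance_type="gain", **params
        )
    from xgboost import XGBClassifier

    return XGBClassifier(
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        importance_type="gain",
        **params,
    )


def stratified_split(
    labels: Iterable[str], train_frac: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell indices into train/test, preserving class proportions.

    Per class the train count is round(train_frac * class size); the
    remainder goes to test. Every class must have at least 2 cells.
    Returns sorted (train_indices, test_indices).
    """
    if not 0 < train_frac < 1:
        raise ValidationError(f"train_frac must be in (0, 1), got {train_frac}")
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValidationError(
                f"class {cls!r} has {len(idx)} cell(s); at least 2 required"
            )
        n_train = int(np.floor(train_frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def _fit_rank(expression, labels, learner, top_k, seed):
    labels = np.asarray(list(labels))
    if len(np.unique(labels)) < 2:
        raise ValidationError("training set has a single class; cannot rank genes")
    if top_k > expression.shape[0]:
        raise ValidationError(
            f"top_k={top_k} exceeds the number of genes ({expression.shape[0]})"
        )
    X = expression.to_numpy(dtype=float).T  # cells x genes
    _, y = np.unique(labels, return_inverse=True)
    est = _make_estimator(learner, seed)
    est.fit(X, y)
    imp = np.asarray(est.feature_importances_, dtype=float)
    gene_ids = np.asarray(expression.index, dtype=object)
    order = np.lexsort((gene_ids, -imp))
    ranked = [(str(gene_ids[i]), float(imp[i])) for i in order[:top_k]]
    return est, ranked


def fit_and_rank(
    expression: pd.DataFrame,
    labels: Iterable[str],
    learner: LearnerSpec,
    top_k: int,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Fit one learner and return its top_k genes by feature importance.

    ``expression`` is genes x cells (rows = genes). Ranking is by the
    learner's native importance, descending, ties broken by gene id.
    """
    _, ranked = _fit_rank(expression, labels, learner, top_k, seed)
    return ranked


def run_consensus(
    expression: pd.DataFrame,
    labels: Iterable[str],
    learner: LearnerSpec,
    n_reps: int = 100,
    top_k: int = 100,
    min_votes: int = 50,
    train_frac: float = 0.7,
    seed: int = 0,
    permute_labels: bool = False,
) -> GeneImportanceTable:
    """Run one learner's repetition/voting protocol.

    Each repetition r: stratified split with seed+r, fit on the training
    cells, record the top_k gene set and importances, and log the held-out
    accuracy (accuracy plays no role in selection). A gene's vote count is
    the number of repetitions whose top_k contained it; its mean importance
    averages over those repetitions. Genes with vote_count >= min_votes are
    selected.

    ``permute_labels=True`` reshuffles the labels independently within each
    repetition (seeded), giving a permutation null for the protocol.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if min_votes > n_reps:
        raise ValidationError(f"min_votes={min_votes} exceeds n_reps={n_reps}")
    labels = np.asarray(list(labels))
    if expression.shape[1] != len(labels):
        raise ValidationError(
            f"expression has {expression.shape[1]} cells but {len(labels)} labels"
        )
    votes: dict[str, int] = {}
    importance_sums: dict[str, float] = {}
    for r in range(n_reps):
        rep_seed = seed + r
        rep_labels = labels
        if permute_labels:
            rep_labels = np.random.default_rng(rep_seed).permutation(labels)
        try:
            train_idx, test_idx = stratified_split(rep_labels, train_frac, seed=rep_seed)
            X_train = expression.iloc[:, train_idx]
            est, ranked = _fit_rank(
                X_train, rep_labels[train_idx], learner, top_k, seed=rep_seed
            )
        except Exception as exc:
            raise RuntimeError(
                f"learner {learner.name!r} failed at repetition {r}: {exc}"
            ) from exc
        for gene, imp in ranked:
            votes[gene] = votes.get(gene, 0) + 1
            importance_sums[gene] = importance_sums.get(gene, 0.0) + imp
        # held-out accuracy is logged for inspection only; selection ignores it
        _, y_all = np.unique(rep_labels, return_inverse=True)
        X_test = expression.to_numpy(dtype=float).T[test_idx]
        acc = float((est.predict(X_test) == y_all[test_idx]).mean())
        logger.debug(
            "learner %s rep %d/%d test accuracy %.3f", learner.name, r + 1, n_reps, acc
        )
    rows = [
        {
            "gene_id": gene,
            "learner": learner.name,
            "vote_count": count,
            "mean_importance": importance_sums[gene] / count,
            "selected": count >= min_votes,
        }
        for gene, count in votes.items()
    ]
    df = pd.DataFrame(rows, columns=list(GeneImportanceTable.COLUMNS))
    df = df.sort_values(
        ["selected", "vote_count", "mean_importance", "gene_id"],
        ascending=[False, False, False, True],
    ).reset_index(drop=True)
    n_sel = int(df["selected"].sum())
    logger.info(
        "learner %s: %d/%d genes selected (votes >= %d of %d reps)",
        learner.name,
        n_sel,
        expression.shape[0],
        min_votes,
        n_reps,
    )
    return GeneImportanceTable(df, n_reps=n_reps, min_votes=min_votes)


def combine_models(
    tables: list[GeneImportanceTable], mode: str = "intersection"
) -> tuple[list[str], dict[str, float]]:
    """Combine per-learner selections into a consensus gene set + weights.

    mode="intersection" (default) keeps genes selected by every learner;
    "union" keeps genes selected by any. The combined importance of a
    consensus gene is the mean over learners of its min-max-rescaled mean
    importance (rescaled within each learner across that learner's table,
    making learners with different importance scales commensurable; a
    learner whose importances are all equal contributes 1.0).
    """
    if not tables:
        raise ValidationError("combine_models needs at least one importance table")
    if mode not in ("intersection", "union"):
        raise ValidationError(f"mode must be 'intersection' or 'union', got {mode!r}")
    selected_sets = [set(t.selected_genes()) for t in tables]
    consensus = set.intersection(*selected_sets) if mode == "intersection" else set.union(
        *selected_sets
    )
    if not consensus:
        logger.warning("consensus gene set is empty; downstream scoring will fail")
        return [], {}
    combined: dict[str, list[float]] = {g: [] for g in consensus}
    for table in tables:
        df = table.df
        imp = df["mean_importance"].to_numpy(dtype=float)
        lo, hi = imp.min(), imp.max()
        rescaled = np.ones_like(imp) if hi == lo else (imp - lo) / (hi - lo)
        by_gene = dict(zip(df["gene_id"], rescaled))
        for g in consensus:
            if g in by_gene:
                combined[g].append(float(by_gene[g]))
    weights = {g: float(np.mean(v)) if v else 0.0 for g, v in combined.items()}
    return sorted(consensus), weights
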