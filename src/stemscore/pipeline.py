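"""End-to-end pipeline orchestration with a config file and a run manifest.

Stages: (optional) simulate -> select-genes -> map-regions -> score ->
label-states. A single top-level seed deterministically derives one seed
per stage (SHA-256 of ``"<seed>:<stage>"``, reduced mod 2^31), so any stage
can be replayed in isolation; the manifest records every derived seed,
all parameters, and the gene/cell counts surviving each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .containers import StemnessResult, ValidationError
from .importance import LEARNER_NAMES, LearnerSpec, combine_models, run_consensus
from .labeling import assign_gsc_state, label_neftel_states, summarize_groups
from .mapping import (
    aggregate_gene_counts,
    average_association,
    log_transform,
    map_regions_to_peaks,
    zscore_filter,
)
from .scoring import compute_weights, score_cells
from .simulate import SimulationSpec, simulate_bundle, write_bundle

logger = logging.getLogger("stemscore")


def derive_seed(seed: int, stage: str) -> int:
    """Stage seed = low 31 bits of sha256("<seed>:<stage>")."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All paths and parameters of one pipeline run.

    Input paths may be omitted when ``simulate=True``; the synthetic bundle
    is then written under ``<out_dir>/inputs`` and used in place of real
    data.
    """

    out_dir: str = "stemscore_run"
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimulationSpec overrides

    expression: str | None = None
    rna_labels: str | None = None
    peaks: str | None = None
    barcodes: str | None = None
    counts: str | None = None
    regions: str | None = None
    signatures: str | None = None
    gsc_regions: str | None = None

    regions_convention: str = "bed0"
    peaks_convention: str = "bed0"
    transpose_counts: bool = False

    models: list[str] = field(default_factory=lambda: ["rf", "gb", "xgb"])
    learner_overrides: dict = field(default_factory=dict)  # name -> hyperparams
    reps: int = 100
    min_votes: int = 50
    top_k: int = 100
    train_frac: float = 0.7
    combine_mode: str = "intersection"
    importance_from: str = "mean"  # mean | rf | gb | xgb

    z_cutoff: float = -1.0
    filter_axis: str = "gene"
    weight_mode: str = "rescale"
    stemness_cutoff: float = 0.5
    k_clusters: int = 3
    linkage: str = "ward"
    metric: str = "euclidean"
    include_enhancers: bool = False
    gsc_signal_mode: str = "mean"

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValidationError("train_frac must lie in (0, 1)")
        if self.min_votes > self.reps:
            raise ValidationError(
                f"min_votes ({self.min_votes}) cannot exceed reps ({self.reps})"
            )
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not self.models:
            raise ValidationError("at least one model is required")
        for m in self.models:
            if m not in LEARNER_NAMES:
                raise ValidationError(f"unknown model {m!r}; choose from {LEARNER_NAMES}")
        if self.combine_mode not in ("intersection", "union"):
            raise ValidationError("combine_mode must be 'intersection' or 'union'")
        if self.importance_from not in ("mean", *LEARNER_NAMES):
            raise ValidationError("importance_from must be 'mean' or a model name")
        if not 0 <= self.stemness_cutoff <= 1:
            raise ValidationError("stemness_cutoff must lie in [0, 1]")
        if self.k_clusters < 2:
            raise ValidationError("k_clusters must be >= 2")
        if not self.simulate:
            required = (
                "expression rna_labels peaks barcodes counts regions "
                "signatures gsc_regions"
            ).split()
            for name in required:
                value = getattr(self, name)
                if value is None:
                    raise ValidationError(f"config field {name!r} is required")
                if not Path(value).exists():
                    raise ValidationError(f"{name} path does not exist: {value}")


def _combined_importance(tables, consensus, combined, importance_from):
    if importance_from == "mean":
        return combined
    for table in tables:
        if table.df["learner"].iloc[0] == importance_from:
            by_gene = dict(zip(table.df["gene_id"], table.df["mean_importance"]))
            return {g: float(by_gene.get(g, 0.0)) for g in consensus}
    raise ValidationError(f"model {importance_from!r} was not run")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``<out_dir>/manifest.json``)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (dict,))
        },
        "seeds": {},
        "stages": {},
    }

    # -- stage 0: inputs ---------------------------------------------------
    if config.simulate:
        sim_seed = derive_seed(config.seed, "simulate")
        manifest["seeds"]["simulate"] = sim_seed
        spec = SimulationSpec(**{**config.sim, "seed": sim_seed})
        bundle = simulate_bundle(spec)
        paths = write_bundle(bundle, out_dir / "inputs")
        config.expression = str(paths["expression"])
        config.rna_labels = str(paths["rna_labels"])
        config.peaks = str(paths["peaks"])
        config.barcodes = str(paths["barcodes"])
        config.counts = str(paths["counts"])
        config.regions = str(paths["regions"])
        config.signatures = str(paths["signatures"])
        config.gsc_regions = str(paths["gsc_regions"])
        manifest["stages"]["simulate"] = {
            "n_cells": bundle.dataset.n_cells,
            "n_peaks": bundle.dataset.n_peaks,
            "n_genes": spec.n_genes,
            "n_stem_cells": len(bundle.truth.stem_cell_barcodes),
        }
        logger.info("stage simulate: wrote synthetic bundle to %s", out_dir / "inputs")

    # -- stage 1: consensus gene selection ---------------------------------
    stage = "select-genes"
    try:
        expression = pd.read_csv(config.expression, sep="\t", index_col=0)
        labels = pd.read_csv(config.rna_labels, sep="\t")["state"].to_numpy()
        tables = []
        for model in config.models:
            model_seed = derive_seed(config.seed, f"consensus:{model}")
            manifest["seeds"][f"consensus:{model}"] = model_seed
            spec_l = LearnerSpec(model, dict(config.learner_overrides.get(model, {})))
            table = run_consensus(
                expression,
                labels,
                spec_l,
                n_reps=config.reps,
                top_k=config.top_k,
                min_votes=config.min_votes,
                train_frac=config.train_frac,
                seed=model_seed,
            )
            sio.write_importance_table(table, out_dir / f"importance_{model}.tsv")
            tables.append(table)
        consensus, combined = combine_models(tables, mode=config.combine_mode)
        importance = _combined_importance(
            tables, consensus, combined, config.importance_from
        )
        if not consensus:
            raise ValidationError(
                "consensus gene set is empty; scoring is undefined "
                "(try combine_mode='union' or lower min_votes)"
            )
        manifest["stages"][stage] = {
            "n_genes_in": int(expression.shape[0]),
            "n_cells": int(expression.shape[1]),
            "selected_per_model": {
                t.df["learner"].iloc[0]: int(t.df["selected"].sum()) for t in tables
            },
            "n_consensus_genes": len(consensus),
        }
        logger.info("stage %s: %d consensus genes", stage, len(consensus))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stage 2: region mapping and aggregation ---------------------------
    stage = "map-regions"
    try:
        dataset = sio.read_peak_count_bundle(
            config.peaks,
            config.barcodes,
            config.counts,
            coord_convention=config.peaks_convention,
            transpose=config.transpose_counts,
        )
        regions = sio.read_gene_regions(
            config.regions, coord_convention=config.regions_convention
        )
        rpmap = map_regions_to_peaks(regions, dataset.peaks)
        mapped = set(rpmap.gene_ids)
        scored_genes = sorted(set(consensus) & mapped)
        dropped = sorted(set(consensus) - mapped)
        if dropped:
            logger.warning(
                "%d consensus gene(s) have no mapped peaks and are dropped: %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        if len(scored_genes) < 2:
            raise ValidationError(
                "fewer than 2 consensus genes map to peaks; cannot score"
            )
        raw = aggregate_gene_counts(rpmap, dataset, gene_set=scored_genes)
        filtered = zscore_filter(raw, z_cutoff=config.z_cutoff, axis=config.filter_axis)
        logged = log_transform(filtered)
        association = average_association(regions, rpmap)
        logged.to_frame().rename_axis("gene_id").to_csv(
            out_dir / "gene_matrix.tsv", sep="\t"
        )
        association.loc[scored_genes].rename_axis("gene_id").to_frame().to_csv(
            out_dir / "association_power.tsv", sep="\t"
        )
        manifest["stages"][stage] = {
            "n_peaks": dataset.n_peaks,
            "n_cells": dataset.n_cells,
            "n_region_peak_links": len(rpmap),
            "n_mapped_genes": len(mapped),
            "n_scored_genes": len(scored_genes),
            "n_consensus_dropped": len(dropped),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stage 3: stemness scoring ------------------------------------------
    stage = "score"
    try:
        weights = compute_weights(
            {g: importance[g] for g in scored_genes},
            association.to_dict(),
            scored_genes,
            mode=config.weight_mode,
        )
        result = score_cells(weights, logged, cutoff=config.stemness_cutoff)
        weights.to_csv(out_dir / "gene_weights.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_cells": len(result.barcodes),
            "n_high_stemness": int((result.stemness_class == "high").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stage 4: state labeling --------------------------------------------
    stage = "label-states"
    try:
        signatures = sio.read_signatures(config.signatures)
        gsc_regions = sio.read_gsc_regions(config.gsc_regions)
        neftel = label_neftel_states(
            signatures,
            regions,
            dataset,
            k=config.k_clusters,
            linkage_method=config.linkage,
            distance_metric=config.metric,
            include_enhancers=config.include_enhancers,
        )
        gsc = assign_gsc_state(
            dataset,
            gsc_regions,
            result,
            cutoff=config.stemness_cutoff,
            signal_mode=config.gsc_signal_mode,
        )
        result = StemnessResult(
            barcodes=result.barcodes,
            raw_score=result.raw_score,
            norm_score=result.norm_score,
            stemness_class=result.stemness_class,
            neftel_state=neftel,
            gsc_state=gsc,
        )
        sio.write_scores(result, out_dir / "scores.tsv")
        summary = summarize_groups(result)
        summary.to_csv(out_dir / "group_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_neftel_assigned": int((neftel != "unassigned").sum()),
            "n_gsc_assigned": int((gsc != "unassigned").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
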