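"""Synthetic fixtures with planted, recoverable structure.

Every pipeline input — labeled scRNA-seq expression, a gene promoter/
enhancer annotation with association scores, a peaks/barcodes/counts
scATAC bundle, state signature lists and GSC discriminating regions — can
be generated here with known ground truth, so each stage and the full
pipeline are testable without any download.

Counts in both modalities are negative-binomial: mean m, dispersion theta,
variance m + m^2/theta. Informative genes carry a ``fold_effect``
multiplicative mean shift in exactly one designated cell state (scRNA-seq),
and cells flagged as stem-like carry the same fold shift at the peaks of
informative genes (scATAC-seq). All draws are deterministic given
``SimulationSpec.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    GSC_STATES,
    GeneRegionTable,
    GenomicInterval,
    GroundTruth,
    GscRegionTable,
    PeakCountDataset,
    StateSignatureTable,
    ValidationError,
)

logger = logging.getLogger("stemscore")

DEFAULT_GENOME_SIZES = {f"chr{i}": 20_000_000 for i in range(1, 6)}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic data.

    Defaults mirror the recovery scenario the pipeline is validated on:
    4 cell states of 100 cells each, 500 genes of which 20 are informative
    with an 8-fold accessibility/expression shift, 5,000 scATAC peaks, a
    20% stem-like cell fraction, and moderate negative-binomial
    overdispersion (theta = 2).
    """

    n_states: int = 4
    cells_per_state: int = 100
    n_genes: int = 500
    n_informative_genes: int = 20
    fold_effect: float = 8.0
    n_peaks: int = 5000
    stem_fraction: float = 0.2
    noise_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.cells_per_state < 1:
            raise ValidationError("cells_per_state must be >= 1")
        if self.n_informative_genes > self.n_genes:
            raise ValidationError("n_informative_genes cannot exceed n_genes")
        if self.fold_effect < 1:
            raise ValidationError("fold_effect must be >= 1")
        if not 0 < self.stem_fraction < 1:
            raise ValidationError("stem_fraction must lie in (0, 1)")
        if self.noise_dispersion <= 0:
            raise ValidationError("noise_dispersion must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_states * self.cells_per_state

    @property
    def state_names(self) -> list[str]:
        if self.n_states == 4:
            # the labeled populations of the training scRNA-seq data
            return ["astrocyte", "qNSC", "aNSC", "NPC"]
        return [f"state{i + 1}" for i in range(self.n_states)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i + 1:04d}" for i in range(self.n_genes)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and dispersion ``theta``."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_scrnaseq(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Labeled scRNA-seq counts with state-informative genes.

    Returns (expression genes x cells, per-cell state labels, ground
    truth). Each informative gene's mean is multiplied by ``fold_effect``
    in exactly one state (informative genes are spread over states round-
    robin); with ``fold_effect=1`` no gene is differential.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    states = spec.state_names
    labels = np.repeat(states, spec.cells_per_state)
    barcodes = [f"rna_cell{i + 1:05d}" for i in range(spec.n_cells)]
    # noise genes are exchangeable (one shared baseline mean): tree-ensemble
    # impurity importances are scale-biased, so per-gene scale heterogeneity
    # would by itself create stable spurious rankings under label-free noise
    base_mean = np.full(spec.n_genes, 2.0)
    informative = sorted(
        rng.choice(spec.n_genes, size=spec.n_informative_genes, replace=False)
    )
    gene_state = {
        genes[g]: states[i % spec.n_states] for i, g in enumerate(informative)
    }
    mean = np.tile(base_mean[:, None], (1, spec.n_cells))
    for g in informative:
        boosted = labels == gene_state[genes[g]]
        mean[g, boosted] *= spec.fold_effect
    counts = _nb_draw(rng, mean, spec.noise_dispersion)
    expression = pd.DataFrame(counts, index=genes, columns=barcodes)
    truth = GroundTruth(
        informative_gene_ids={genes[g] for g in informative},
        informative_gene_states=gene_state,
    )
    return expression, labels, truth


def simulate_gene_regions(
    gene_ids: list[str],
    genome_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> GeneRegionTable:
    """One promoter plus 0-3 enhancers per gene, with gamma-distributed
    association scores (shape 2, scale 5)."""
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("gene_ids must be unique")
    genome_sizes = dict(genome_sizes or DEFAULT_GENOME_SIZES)
    chroms = sorted(genome_sizes)
    rng = np.random.default_rng(seed)
    rows = []
    for gene in gene_ids:
        chrom = chroms[rng.integers(len(chroms))]
        size = genome_sizes[chrom]
        anchor = int(rng.integers(200_000, size - 200_000))
        prom_len = int(rng.integers(500, 2000))
        rows.append(
            (gene, chrom, anchor, anchor + prom_len, "promoter",
             float(rng.gamma(2.0, 5.0)))
        )
        for _ in range(int(rng.integers(0, 4))):
            offset = int(rng.integers(-100_000, 100_000))
            start = max(0, anchor + offset)
            enh_len = int(rng.integers(200, 1000))
            rows.append(
                (gene, chrom, start, start + enh_len, "enhancer",
                 float(rng.gamma(2.0, 5.0)))
            )
    df = pd.DataFrame(rows, columns=list(GeneRegionTable.COLUMNS))
    return GeneRegionTable(df)


def _decoy_peaks(
    rng: np.random.Generator,
    n_decoys: int,
    genome_sizes: dict[str, int],
    region_midpoints: dict[str, np.ndarray],
    clearance: int = 2000,
) -> list[GenomicInterval]:
    """Peaks guaranteed to be at least ``clearance`` bp away from every
    gene-region midpoint, so they map to no gene."""
    chroms = sorted(genome_sizes)
    decoys: list[GenomicInterval] = []
    while len(decoys) < n_decoys:
        chrom = chroms[rng.integers(len(chroms))]
        size = genome_sizes[chrom]
        start = int(rng.integers(0, size - 1000))
        width = int(rng.integers(200, 800))
        mids = region_midpoints.get(chrom)
        if mids is not None and mids.size:
            lo = np.searchsorted(mids, start - clearance)
            hi = np.searchsorted(mids, start + width + clearance)
            if hi > lo:  # a region midpoint is too close
                continue
        decoys.append(GenomicInterval(chrom, start, start + width))
    return decoys


def simulate_scatac_bundle(
    spec: SimulationSpec,
    gene_regions: GeneRegionTable,
    informative_gene_ids: set[str],
    informative_gene_states: dict[str, str] | None = None,
    plant_states: bool = False,
    genome_sizes: dict[str, int] | None = None,
) -> tuple[PeakCountDataset, GroundTruth]:
    """A peaks/barcodes/counts bundle with a planted stem-like population.

    One peak is generated around the midpoint of every gene region (so the
    midpoint-in-peak test links it back to its gene), and decoy peaks that
    map to nothing fill the bundle up to ``spec.n_peaks``. A fraction
    ``stem_fraction`` of cells is stem-like: their negative-binomial mean
    at the peaks of informative genes is multiplied by ``fold_effect``.

    With ``plant_states=True`` each stem cell additionally receives a
    second ``fold_effect`` boost at the peaks of its own signature state's
    genes (states taken from ``informative_gene_states``), and a GSC
    functional state derived from that signature state; this layer supports
    state-labeling recovery tests and is off by default so the plain
    stem/non-stem contrast stays exactly ``fold_effect``.
    """
    if not len(gene_regions):
        raise ValidationError("gene_regions must be non-empty")
    genome_sizes = dict(genome_sizes or DEFAULT_GENOME_SIZES)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    rdf = gene_regions.df

    peaks: list[GenomicInterval] = []
    peak_gene: list[str | None] = []
    for rec in rdf.itertuples(index=False):
        mid = (int(rec.start) + int(rec.end)) // 2
        left = int(rng.integers(100, 400))
        right = int(rng.integers(100, 400))
        peaks.append(GenomicInterval(str(rec.chrom), max(0, mid - left), mid + right))
        peak_gene.append(rec.gene_id)
    n_decoys = spec.n_peaks - len(peaks)
    if n_decoys < 0:
        logger.warning(
            "n_peaks=%d is below the %d region peaks; emitting no decoys",
            spec.n_peaks,
            len(peaks),
        )
        n_decoys = 0
    region_mids = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in rdf.groupby("chrom")
    }
    decoys = _decoy_peaks(rng, n_decoys, genome_sizes, region_mids)
    peaks.extend(decoys)
    peak_gene.extend([None] * len(decoys))

    n_cells = spec.n_cells
    barcodes = [f"cell{i + 1:05d}" for i in range(n_cells)]
    n_stem = max(1, int(round(spec.stem_fraction * n_cells)))
    stem_idx = np.sort(rng.choice(n_cells, size=n_stem, replace=False))
    stem_mask = np.zeros(n_cells, dtype=bool)
    stem_mask[stem_idx] = True

    base = rng.gamma(shape=2.0, scale=0.25, size=len(peaks))  # per-peak mean ~0.5
    mean = np.tile(base[:, None], (1, n_cells))
    informative_peaks = np.array(
        [g is not None and g in informative_gene_ids for g in peak_gene]
    )
    mean[np.ix_(informative_peaks, stem_mask)] *= spec.fold_effect

    truth = GroundTruth(
        informative_gene_ids=set(informative_gene_ids),
        stem_cell_barcodes={barcodes[i] for i in stem_idx},
        informative_gene_states=dict(informative_gene_states or {}),
    )
    if plant_states:
        if not informative_gene_states:
            raise ValidationError(
                "plant_states=True requires informative_gene_states"
            )
        states = sorted(set(informative_gene_states.values()))
        gsc_of_state = {s: GSC_STATES[i % len(GSC_STATES)] for i, s in enumerate(states)}
        cell_states = rng.choice(states, size=n_stem)
        for i, state in zip(stem_idx, cell_states):
            state_peaks = np.array(
                [
                    g is not None and informative_gene_states.get(g) == state
                    for g in peak_gene
                ]
            )
            mean[state_peaks, i] *= spec.fold_effect
            truth.true_state_per_cell[barcodes[i]] = str(state)
            truth.true_gsc_state_per_cell[barcodes[i]] = gsc_of_state[str(state)]

    counts = sp.csr_matrix(_nb_draw(rng, mean, spec.noise_dispersion))
    dataset = PeakCountDataset(peaks=peaks, barcodes=barcodes, counts=counts)
    return dataset, truth


def make_signatures(informative_gene_states: dict[str, str]) -> StateSignatureTable:
    """Signature table: each state's signature genes are its informative genes."""
    rows = sorted((s, g) for g, s in informative_gene_states.items())
    return StateSignatureTable(pd.DataFrame(rows, columns=["state", "gene_id"]))


def make_gsc_regions(
    gene_regions: GeneRegionTable,
    informative_gene_states: dict[str, str],
    half_width: int = 600,
) -> GscRegionTable:
    """GSC discriminating regions around informative-gene region midpoints.

    Signature states map onto the three GSC states round-robin; each
    informative region contributes one interval of +/- ``half_width``
    around its midpoint, wide enough to contain the midpoint of the peak
    generated over the same region.
    """
    states = sorted(set(informative_gene_states.values()))
    gsc_of_state = {s: GSC_STATES[i % len(GSC_STATES)] for i, s in enumerate(states)}
    rows = []
    for rec in gene_regions.df.itertuples(index=False):
        state = informative_gene_states.get(rec.gene_id)
        if state is None:
            continue
        mid = (int(rec.start) + int(rec.end)) // 2
        rows.append(
            (str(rec.chrom), max(0, mid - half_width), mid + half_width,
             gsc_of_state[state])
        )
    return GscRegionTable(pd.DataFrame(rows, columns=list(GscRegionTable.COLUMNS)))


@dataclass
class SimulatedBundle:
    """Everything one pipeline run needs, plus the planted ground truth."""

    spec: SimulationSpec
    expression: pd.DataFrame
    rna_labels: np.ndarray
    gene_regions: GeneRegionTable
    dataset: PeakCountDataset
    signatures: StateSignatureTable
    gsc_regions: GscRegionTable
    truth: GroundTruth


def simulate_bundle(spec: SimulationSpec, plant_states: bool = True) -> SimulatedBundle:
    """Generate a complete, mutually consistent set of pipeline inputs."""
    expression, rna_labels, rna_truth = simulate_scrnaseq(spec)
    gene_regions = simulate_gene_regions(spec.gene_ids, seed=spec.seed + 1)
    dataset, truth = simulate_scatac_bundle(
        spec,
        gene_regions,
        rna_truth.informative_gene_ids,
        informative_gene_states=rna_truth.informative_gene_states,
        plant_states=plant_states,
    )
    signatures = make_signatures(rna_truth.informative_gene_states)
    gsc_regions = make_gsc_regions(
        gene_regions.subset(gene_ids=rna_truth.informative_gene_ids),
        rna_truth.informative_gene_states,
    )
    return SimulatedBundle(
        spec=spec,
        expression=expression,
        rna_labels=rna_labels,
        gene_regions=gene_regions,
        dataset=dataset,
        signatures=signatures,
        gsc_regions=gsc_regions,
        truth=truth,
    )


def write_bundle(bundle: SimulatedBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as the plain-text files the CLI consumes."""
    from . import io as sio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sio.write_peak_count_bundle(bundle.dataset, out_dir)
    paths["regions"] = out_dir / "regions.tsv"
    sio.write_gene_regions(bundle.gene_regions, paths["regions"])
    paths["signatures"] = out_dir / "signatures.tsv"
    sio.write_signatures(bundle.signatures, paths["signatures"])
    paths["gsc_regions"] = out_dir / "gsc_regions.bed"
    sio.write_gsc_regions(bundle.gsc_regions, paths["gsc_regions"])
    paths["expression"] = out_dir / "expression.tsv"
    bundle.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    paths["rna_labels"] = out_dir / "rna_labels.tsv"
    pd.DataFrame(
        {"barcode": bundle.expression.columns, "state": bundle.rna_labels}
    ).to_csv(paths["rna_labels"], sep="\t", index=False)
    paths["truth"] = out_dir / "truth.tsv"
    truth = bundle.truth
    pd.DataFrame(
        {
            "barcode": bundle.dataset.barcodes,
            "is_stem": [b in truth.stem_cell_barcodes for b in bundle.dataset.barcodes],
            "true_state": [
                truth.true_state_per_cell.get(b, "") for b in bundle.dataset.barcodes
            ],
            "true_gsc_state": [
                truth.true_gsc_state_per_cell.get(b, "") for b in bundle.dataset.barcodes
            ],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
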