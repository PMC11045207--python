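import numpy as np
import pytest

import stemscore as ss


@pytest.fixture(scope="session")
def small_spec():
    return ss.SimulationSpec(
        n_states=2,
        cells_per_state=25,
        n_genes=40,
        n_informative_genes=8,
        fold_effect=8.0,
        n_peaks=250,
        stem_fraction=0.2,
        noise_dispersion=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """A small but complete synthetic input bundle with planted structure."""
    return ss.simulate_bundle(small_spec)


def random_peaks(rng, n_peaks, chroms=("chr1", "chr2"), span=10_000):
    peaks = []
    for _ in range(n_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        peaks.append(ss.GenomicInterval(chrom, start, start + int(rng.integers(50, 400))))
    return peaks


def random_regions(rng, n_regions, chroms=("chr1", "chr2"), span=10_000):
    import pandas as pd

    rows = []
    for i in range(n_regions):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        rows.append(
            (
                f"g{rng.integers(1, max(2, n_regions // 2))}",
                chrom,
                start,
                start + int(rng.integers(20, 300)),
                ("promoter", "enhancer")[rng.integers(2)],
                float(rng.gamma(2.0, 5.0)),
            )
        )
    df = pd.DataFrame(rows, columns=list(ss.GeneRegionTable.COLUMNS))
    df = df.drop_duplicates(subset=["gene_id", "chrom", "start", "end", "element_type"])
    return ss.GeneRegionTable(df)


def random_dataset(rng, peaks, n_cells, max_count=10):
    import scipy.sparse as sp

    counts = rng.integers(0, max_count, size=(len(peaks), n_cells))
    return ss.PeakCountDataset(
        peaks=peaks,
        barcodes=[f"bc{i}" for i in range(n_cells)],
        counts=sp.csr_matrix(counts),
    )
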