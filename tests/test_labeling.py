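import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import stemscore as ss
from stemscore.containers import GSC_STATES, UNASSIGNED, ValidationError
from stemscore.labeling import assign_state_cluster
from stemscore.mapping import midpoint


def brute_force_gsc(dataset, gsc_regions, norm_scores, cutoff):
    """Independent re-implementation of the GSC argmax assignment."""
    dense = dataset.counts.toarray()
    states = [s for s in GSC_STATES if s in set(gsc_regions.df["gsc_state"])]
    out = []
    for c in range(dataset.n_cells):
        if norm_scores[c] < cutoff:
            out.append(UNASSIGNED)
            continue
        signals = {}
        for state in states:
            regs = gsc_regions.df[gsc_regions.df["gsc_state"] == state]
            total = 0
            for p, peak in enumerate(dataset.peaks):
                mid = midpoint(peak)
                for rec in regs.itertuples(index=False):
                    if (
                        str(rec.chrom) == peak.chrom
                        and int(rec.start) <= mid < int(rec.end)
                    ):
                        total += dense[p, c]
                        break
            signals[state] = total / len(regs)
        best = max(signals.values())
        winners = [s for s in states if signals[s] == best]
        out.append(winners[0] if len(winners) == 1 else UNASSIGNED)
    return np.array(out, dtype=object)


def make_result(barcodes, norm):
    norm = np.asarray(norm, dtype=float)
    return ss.StemnessResult(
        barcodes=list(barcodes),
        raw_score=norm,
        norm_score=norm,
        stemness_class=ss.classify_stemness(norm),
    )


class TestSignatureAccessibility:
    def test_single_gene_reduces_to_aggregated_logged_counts(self, small_bundle):
        sig = small_bundle.signatures
        state = sig.states[0]
        gene = sig.genes_for(state)[0]
        one = ss.StateSignatureTable(pd.DataFrame({"state": [state], "gene_id": [gene]}))
        matrix = ss.signature_accessibility(
            one, small_bundle.gene_regions, small_bundle.dataset, state
        )
        assert matrix.gene_ids == [gene] and matrix.stage == "logged"

    def test_matches_composed_map_aggregate_log_chain(self, small_bundle):
        sig, regions, ds = (
            small_bundle.signatures,
            small_bundle.gene_regions,
            small_bundle.dataset,
        )
        state = sig.states[0]
        matrix = ss.signature_accessibility(sig, regions, ds, state)
        promoters = regions.subset(
            gene_ids=sig.genes_for(state), element_types=["promoter"]
        )
        rpmap = ss.map_regions_to_peaks(promoters, ds.peaks)
        expected = ss.log_transform(
            ss.aggregate_gene_counts(rpmap, ds, gene_set=matrix.gene_ids)
        )
        np.testing.assert_allclose(matrix.values, expected.values)

    def test_state_with_no_mappable_genes_is_fatal(self, small_bundle):
        sig = ss.StateSignatureTable(
            pd.DataFrame({"state": ["ghost"], "gene_id": ["no_such_gene"]})
        )
        with pytest.raises(ValidationError, match="ghost"):
            ss.signature_accessibility(
                sig, small_bundle.gene_regions, small_bundle.dataset, "ghost"
            )


class TestClusterCells:
    def planted_matrix(self, n_low=30, n_high=20, seed=0, mean_high=8.0):
        rng = np.random.default_rng(seed)
        low = rng.poisson(1.0, size=(10, n_low))
        high = rng.poisson(mean_high, size=(10, n_high))
        values = np.hstack([low, high]).astype(float)
        return ss.GeneCellMatrix(
            [f"g{i}" for i in range(10)],
            [f"c{i}" for i in range(n_low + n_high)],
            values,
        )

    def test_recovers_two_planted_blobs(self):
        matrix = self.planted_matrix()
        clusters = ss.cluster_cells(matrix, k=2)
        labels = clusters.cluster_id
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_cells_gives_singletons(self):
        matrix = self.planted_matrix(n_low=3, n_high=3)
        clusters = ss.cluster_cells(matrix, k=6)
        assert sorted(clusters.cluster_id) == [1, 2, 3, 4, 5, 6]

    def test_duplicate_columns_cluster_together(self):
        values = np.array([[1.0, 1.0, 9.0], [2.0, 2.0, 8.0]])
        matrix = ss.GeneCellMatrix(["g1", "g2"], ["a", "b", "c"], values)
        clusters = ss.cluster_cells(matrix, k=2)
        assert clusters.cluster_id[0] == clusters.cluster_id[1]

    def test_k_above_n_cells_fatal(self):
        matrix = self.planted_matrix(n_low=2, n_high=2)
        with pytest.raises(ValidationError, match="exceeds"):
            ss.cluster_cells(matrix, k=5)


class TestAssignStateCluster:
    def test_argmax_cluster_flagged(self):
        values = np.array([[0.2, 0.2, 3.1, 3.1, 0.4]])
        matrix = ss.GeneCellMatrix(["g"], list("abcde"), values)
        clusters = ss.ClusterResult(np.array([1, 1, 2, 2, 3]), 3, "ward", "euclidean")
        members = assign_state_cluster(clusters, matrix)
        assert members.tolist() == [False, False, True, True, False]

    def test_tie_goes_to_smaller_cluster_id(self):
        values = np.array([[1.0, 1.0]])
        matrix = ss.GeneCellMatrix(["g"], ["a", "b"], values)
        clusters = ss.ClusterResult(np.array([1, 2]), 2, "ward", "euclidean")
        members = assign_state_cluster(clusters, matrix)
        assert members.tolist() == [True, False]

    def test_planted_subpopulation_recovered(self):
        """Cluster-then-flag finds a fold-8 high-accessibility subpopulation."""
        rng = np.random.default_rng(17)
        values = np.hstack(
            [rng.poisson(1.0, size=(8, 60)), rng.poisson(8.0, size=(8, 20))]
        ).astype(float)
        matrix = ss.GeneCellMatrix(
            [f"g{i}" for i in range(8)], [f"c{i}" for i in range(80)], values
        )
        clusters = ss.cluster_cells(matrix, k=2)
        members = assign_state_cluster(clusters, matrix)
        truth = np.array([False] * 60 + [True] * 20)
        agreement = (members == truth).mean()
        assert agreement >= 0.95


class TestAssignGscState:
    def small_instance(self):
        peaks = [
            ss.GenomicInterval("chr1", 0, 100),     # mid 50
            ss.GenomicInterval("chr1", 200, 300),   # mid 250
            ss.GenomicInterval("chr1", 400, 500),   # mid 450
        ]
        gsc = ss.GscRegionTable(
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * 4,
                    "start": [0, 40, 240, 440],
                    "end": [60, 110, 260, 460],
                    "gsc_state": ["constructive", "constructive", "invasive", "reactive"],
                }
            )
        )
        return peaks, gsc

    def test_argmax_of_region_normalized_means(self):
        peaks, gsc = self.small_instance()
        ds = ss.PeakCountDataset(
            peaks=peaks, barcodes=["c1"], counts=sp.csr_matrix([[10], [3], [0]])
        )
        # constructive: peak 0 counted once though 2 regions hit -> 10/2 = 5
        # invasive: 3/1 = 3; reactive: 0/1 = 0
        out = ss.assign_gsc_state(ds, gsc, make_result(["c1"], [0.9]))
        assert out.tolist() == ["constructive"]

    def test_low_stemness_cell_unassigned(self):
        peaks, gsc = self.small_instance()
        ds = ss.PeakCountDataset(
            peaks=peaks, barcodes=["c1"], counts=sp.csr_matrix([[10], [3], [0]])
        )
        out = ss.assign_gsc_state(ds, gsc, make_result(["c1"], [0.3]))
        assert out.tolist() == [UNASSIGNED]

    def test_tied_signals_left_unassigned(self):
        peaks, gsc = self.small_instance()
        ds = ss.PeakCountDataset(
            peaks=peaks, barcodes=["c1"], counts=sp.csr_matrix([[0], [0], [0]])
        )
        out = ss.assign_gsc_state(ds, gsc, make_result(["c1"], [0.9]))
        assert out.tolist() == [UNASSIGNED]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        n_peaks, n_cells = int(rng.integers(5, 30)), int(rng.integers(2, 10))
        peaks = []
        for _ in range(n_peaks):
            start = int(rng.integers(0, 5000))
            peaks.append(ss.GenomicInterval("chr1", start, start + int(rng.integers(20, 200))))
        rows = []
        for _ in range(int(rng.integers(3, 15))):
            start = int(rng.integers(0, 5000))
            rows.append(
                ("chr1", start, start + int(rng.integers(50, 500)),
                 GSC_STATES[rng.integers(3)])
            )
        # ensure every state has at least one region
        for s in GSC_STATES:
            start = int(rng.integers(0, 5000))
            rows.append(("chr1", start, start + 100, s))
        gsc = ss.GscRegionTable(pd.DataFrame(rows, columns=list(ss.GscRegionTable.COLUMNS)))
        counts = sp.csr_matrix(rng.integers(0, 8, size=(n_peaks, n_cells)))
        ds = ss.PeakCountDataset(
            peaks=peaks, barcodes=[f"c{i}" for i in range(n_cells)], counts=counts
        )
        norm = rng.random(n_cells)
        got = ss.assign_gsc_state(ds, gsc, make_result(ds.barcodes, norm), cutoff=0.5)
        expected = brute_force_gsc(ds, gsc, norm, cutoff=0.5)
        np.testing.assert_array_equal(got, expected)

    def test_filter_contract_no_low_cell_gets_a_state(self, small_bundle):
        rng = np.random.default_rng(9)
        norm = rng.random(small_bundle.dataset.n_cells)
        out = ss.assign_gsc_state(
            small_bundle.dataset,
            small_bundle.gsc_regions,
            make_result(small_bundle.dataset.barcodes, norm),
            cutoff=0.5,
        )
        assert all(out[i] == UNASSIGNED for i in np.flatnonzero(norm < 0.5))


class TestLabelNeftelStates:
    def test_planted_state_cells_recovered(self):
        """Stem cells of each planted state get flagged by their own signature."""
        spec = ss.SimulationSpec(
            n_states=2, cells_per_state=60, n_genes=40, n_informative_genes=10,
            fold_effect=8.0, n_peaks=300, stem_fraction=0.25, seed=51,
        )
        bundle = ss.simulate_bundle(spec, plant_states=True)
        labels = ss.label_neftel_states(
            bundle.signatures, bundle.gene_regions, bundle.dataset, k=3
        )
        truth = bundle.truth.true_state_per_cell
        hits = sum(
            labels[i] == truth[bc]
            for i, bc in enumerate(bundle.dataset.barcodes)
            if bc in truth
        )
        assert hits / len(truth) >= 0.9

    def test_multi_state_conflict_resolved_by_larger_accessibility(self, small_bundle):
        labels = ss.label_neftel_states(
            small_bundle.signatures,
            small_bundle.gene_regions,
            small_bundle.dataset,
            k=3,
        )
        assert set(labels) <= set(small_bundle.signatures.states) | {UNASSIGNED}


class TestSummarizeGroups:
    def test_single_cell_group(self):
        res = make_result(["c1"], [0.7])
        out = ss.summarize_groups(
            res,
            neftel_state=np.array(["MES"], dtype=object),
            gsc_state=np.array(["constructive"], dtype=object),
        )
        row = out[(out["gsc_state"] == "constructive") & (out["neftel_state"] == "MES")]
        assert row["n"].iloc[0] == 1 and row["mean"].iloc[0] == pytest.approx(0.7)

    def test_permutation_invariance_of_group_means(self):
        rng = np.random.default_rng(12)
        n = 40
        norm = rng.random(n)
        neftel = rng.choice(["MES", "NPC"], size=n).astype(object)
        gsc = rng.choice(["constructive", "invasive"], size=n).astype(object)
        res = make_result([f"c{i}" for i in range(n)], norm)
        a = ss.summarize_groups(res, neftel_state=neftel, gsc_state=gsc)
        perm = rng.permutation(n)
        res_p = make_result([f"c{i}" for i in perm], norm[perm])
        b = ss.summarize_groups(res_p, neftel_state=neftel[perm], gsc_state=gsc[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_row_has_n_zero(self):
        res = make_result(["c1", "c2"], [0.1, 0.9])
        out = ss.summarize_groups(
            res,
            neftel_state=np.array(["MES", "NPC"], dtype=object),
            gsc_state=np.array(["constructive", UNASSIGNED], dtype=object),
        )
        empty = out[(out["gsc_state"] == "constructive") & (out["neftel_state"] == "NPC")]
        assert empty["n"].iloc[0] == 0 and np.isnan(empty["mean"].iloc[0])

    def test_planted_state_group_scores_highest(self):
        """Cells carrying the boosted signature score above other groups."""
        spec = ss.SimulationSpec(
            n_states=2, cells_per_state=60, n_genes=40, n_informative_genes=10,
            fold_effect=8.0, n_peaks=300, stem_fraction=0.25, seed=61,
        )
        bundle = ss.simulate_bundle(spec, plant_states=True)
        rpmap = ss.map_regions_to_peaks(bundle.gene_regions, bundle.dataset.peaks)
        genes = sorted(bundle.truth.informative_gene_ids & set(rpmap.gene_ids))
        logged = ss.log_transform(
            ss.zscore_filter(ss.aggregate_gene_counts(rpmap, bundle.dataset, genes))
        )
        rng = np.random.default_rng(0)
        weights = ss.compute_weights(
            dict(zip(genes, rng.random(len(genes)) + 0.1)),
            ss.average_association(bundle.gene_regions, rpmap).to_dict(),
            genes,
        )
        res = ss.score_cells(weights, logged)
        truth = bundle.truth
        is_stem = np.array(
            [b in truth.stem_cell_barcodes for b in bundle.dataset.barcodes]
        )
        stem_label = np.where(is_stem, "stem", "non-stem").astype(object)
        out = ss.summarize_groups(res, neftel_state=stem_label)
        means = out.set_index("neftel_state")["mean"]
        assert means["stem"] > means["non-stem"]
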