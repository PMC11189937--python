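"""Expression-dosage channel: binning, smoothing, clustering, deletion calls."""

import numpy as np
import pandas as pd
import pytest

import del5q
from del5q.expression import (
    _shrinking_moving_average,
    _two_means_1d,
    call_deletion_clusters,
    cluster_cells,
)

from conftest import small_config


class TestAssignBins:
    @pytest.mark.parametrize(
        "start,expected_bin",
        [(219_999, 0), (220_000, 1), (550_000, 2)],
    )
    def test_half_open_boundaries(self, start, expected_bin, monkeypatch):
        genome = del5q.build_genome(small_config(n_genes=40, n_region_genes=10))
        genome.genes.loc[0, ["chromosome", "start_bp", "end_bp"]] = ["1", start, start + 100]
        gene_bin, bins = del5q.assign_bins(genome, bin_size=220_000)
        b = bins.iloc[gene_bin[0]]
        assert b["chromosome"] == "1"
        assert b["start_bp"] == expected_bin * 220_000

    def test_every_gene_mapped_to_exactly_one_bin(self):
        genome = del5q.build_genome(small_config())
        gene_bin, bins = del5q.assign_bins(genome, 220_000)
        assert (gene_bin >= 0).all()
        starts = genome.genes["start_bp"].to_numpy()
        mapped = bins.iloc[gene_bin]
        assert (mapped["start_bp"].to_numpy() <= starts).all()
        assert (starts < mapped["end_bp"].to_numpy()).all()

    def test_invalid_bin_size(self):
        genome = del5q.build_genome(small_config())
        with pytest.raises(ValueError):
            del5q.assign_bins(genome, 0)


class TestSmoothing:
    def test_halfwidth_zero_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 11))
        np.testing.assert_array_equal(_shrinking_moving_average(x, 0), x)

    def test_window_shrinks_at_ends(self):
        x = np.arange(7.0)[None, :]
        sm = _shrinking_moving_average(x, 2)
        assert sm[0, 0] == pytest.approx(np.mean([0, 1, 2]))  # 3-wide at edge
        assert sm[0, 3] == pytest.approx(np.mean([1, 2, 3, 4, 5]))  # full 5-wide
        assert sm[0, 6] == pytest.approx(np.mean([4, 5, 6]))


class TestBinScores:
    def test_null_scores_centered_on_zero(self, null_cohort):
        norm = del5q.normalize_log(null_cohort.counts)
        meta = null_cohort.meta
        ref = meta.loc[meta["condition"] == "healthy", "cell_id"]
        scored = meta.loc[meta["sample_id"] == "MDS_1", "cell_id"]
        bm = del5q.bin_scores(norm, ref, null_cohort.genome, cells=scored)
        region = bm.scores[:, bm.region_bin_mask(null_cohort.genome)]
        grand = region.mean()
        se = region.mean(axis=1).std() / np.sqrt(region.shape[0])
        assert abs(grand) < 3 * max(se, 1e-6)

    def test_deleted_cells_score_negative(self, cohort, normed):
        meta = cohort.meta
        ref = meta.loc[meta["condition"] == "healthy", "cell_id"]
        sub = meta[meta["sample_id"] == "MDS_2"]
        bm = del5q.bin_scores(normed, ref, cohort.genome, cells=sub["cell_id"])
        region = bm.scores[:, bm.region_bin_mask(cohort.genome)].mean(axis=1)
        is_del = (sub["truth_genotype"] == "del").to_numpy()
        assert region[is_del].mean() < -0.05
        assert region[is_del].mean() < region[~is_del].mean()

    def test_gene_order_permutation_invariant(self, cohort, normed):
        """Permuting gene columns (and the annotation) leaves scores unchanged."""
        rng = np.random.default_rng(3)
        perm = rng.permutation(normed.n_genes)
        normed_p = del5q.ExpressionMatrix(
            values=normed.values[:, perm].tocsr(),
            cell_ids=normed.cell_ids,
            gene_ids=normed.gene_ids[perm],
        )
        genome_p = del5q.GenomeAnnotation(
            genes=cohort.genome.genes.iloc[perm].reset_index(drop=True),
            snps=cohort.genome.snps,
            target_region=cohort.genome.target_region,
        )
        ref = cohort.meta.loc[cohort.meta["condition"] == "healthy", "cell_id"]
        cells = cohort.meta.loc[cohort.meta["sample_id"] == "MDS_1", "cell_id"][:50]
        a = del5q.bin_scores(normed, ref, cohort.genome, cells=cells)
        b = del5q.bin_scores(normed_p, ref, genome_p, cells=cells)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_empty_reference_rejected(self, cohort, normed):
        with pytest.raises(ValueError):
            del5q.bin_scores(normed, [], cohort.genome)


class TestClustering:
    @staticmethod
    def _blob_matrix(seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(-0.5, 0.02, size=(30, 8))
        b = rng.normal(0.0, 0.02, size=(30, 8))
        scores = np.vstack([a, b])
        bins = pd.DataFrame(
            {"chromosome": "5", "start_bp": np.arange(8) * 100,
             "end_bp": np.arange(1, 9) * 100, "bin_id": np.arange(8)}
        )
        return del5q.BinMatrix(
            scores=scores, bins=bins, bin_size=100,
            cell_ids=pd.Index([f"c{i}" for i in range(60)]),
        )

    def test_two_blobs_perfect_partition(self):
        bm = self._blob_matrix()
        labels, centroids, degen = cluster_cells(bm, np.ones(8, bool), k=2, seed=0)
        assert not degen
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k_clamped_with_warning(self):
        bm = self._blob_matrix()
        with pytest.warns(UserWarning, match="clamping"):
            labels, _, _ = cluster_cells(bm, np.ones(8, bool), k=80, seed=0)
        assert labels.max() + 1 <= 60

    def test_identical_rows_degenerate(self):
        bm = self._blob_matrix()
        bm.scores[:] = 0.25
        labels, centroids, degen = cluster_cells(bm, np.ones(8, bool), k=5, seed=0)
        assert degen and len(centroids) == 1

    def test_seeded_determinism(self):
        bm = self._blob_matrix(seed=4)
        l1, c1, _ = cluster_cells(bm, np.ones(8, bool), k=6, seed=9)
        l2, c2, _ = cluster_cells(bm, np.ones(8, bool), k=6, seed=9)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(c1, c2)


class TestDeletionCalls:
    def test_noise_level_centroids_all_neutral(self):
        labels = np.array([0, 0, 1, 1, 2])
        centroids = np.array([-0.02, 0.01, 0.0])
        res = call_deletion_clusters(labels, centroids, pd.Index(list("abcde")),
                                     cutoff=-0.05)
        assert (res.calls["expression_call"] == "neutral").all()

    def test_low_group_below_cutoff_deleted(self):
        labels = np.array([0, 1, 1, 0, 2])
        centroids = np.array([-0.5, 0.0, -0.45])
        res = call_deletion_clusters(labels, centroids, pd.Index(list("abcde")),
                                     cutoff=-0.1)
        calls = res.calls.set_index("cell_id")["expression_call"]
        assert calls["a"] == "deleted" and calls["e"] == "deleted"
        assert calls["b"] == "neutral"

    def test_single_centroid_compared_directly(self):
        res = call_deletion_clusters(np.zeros(3, int), np.array([-0.3]),
                                     pd.Index(list("xyz")), cutoff=-0.05)
        assert (res.calls["expression_call"] == "deleted").all()

    def test_two_means_1d_recovers_split(self):
        v = np.array([-0.52, -0.48, -0.5, 0.01, -0.02, 0.03])
        lower = _two_means_1d(v)
        np.testing.assert_array_equal(lower, v < -0.2)


class TestChannelEndToEnd:
    def test_negative_control_calls_nothing(self, null_cohort):
        norm = del5q.normalize_log(null_cohort.counts)
        res = del5q.expression_channel(norm, null_cohort.meta, null_cohort.genome,
                                       k=12, seed=0)
        frac = (res.calls["expression_call"] == "deleted").mean()
        assert frac <= 0.01

    def test_recovers_truth_with_dosage_half(self, cohort, channel_calls):
        merged = channel_calls
        sens = (
            (merged.loc[merged["truth_genotype"] == "del", "expression_call"]
             == "deleted").mean()
        )
        spec = (
            (merged.loc[merged["truth_genotype"] == "non_del", "expression_call"]
             == "neutral").mean()
        )
        assert sens >= 0.9 and spec >= 0.9

    def test_sensitivity_monotone_in_dosage(self):
        """Deeper dosage loss never hurts deletion sensitivity."""
        sens = []
        for dosage in (1.0, 0.8, 0.6, 0.5):
            ds = del5q.simulate(
                small_config(seed=2024, dosage_factor=dosage,
                             n_samples=1, del_fraction_per_sample=(0.5,),
                             cells_per_sample=300, reference_cells_per_sample=300)
            )
            norm = del5q.normalize_log(ds.counts)
            res = del5q.expression_channel(norm, ds.meta, ds.genome, k=15, seed=1)
            merged = res.calls.merge(ds.meta, on="cell_id")
            sens.append(
                (merged.loc[merged["truth_genotype"] == "del", "expression_call"]
                 == "deleted").mean()
            )
        assert all(b >= a - 1e-9 for a, b in zip(sens, sens[1:]))
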