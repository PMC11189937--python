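"""Pseudobulk NB GLM LRT, hurdle test, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.sparse as sp
import scipy.special
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import del5q
from del5q.de import PseudobulkMatrix, bh_adjust, hurdle_lrt, make_pseudobulk, nb_glm_lrt


def pb_from(counts, groups):
    counts = np.asarray(counts)
    return PseudobulkMatrix(
        counts=counts.astype(np.int64),
        replicates=pd.DataFrame(
            {
                "sample_id": [f"r{i}" for i in range(len(groups))],
                "cell_type": "x",
                "group": groups,
                "n_cells": 100,
            }
        ),
        gene_ids=pd.Index([f"g{j}" for j in range(counts.shape[1])]),
    )


def nb_loglik_oracle(y, mu, phi):
    """Direct NB log-likelihood (var = mu + phi mu^2)."""
    r = 1.0 / phi
    return float(
        np.sum(
            scipy.special.gammaln(y + r)
            - scipy.special.gammaln(r)
            - scipy.special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


class TestMakePseudobulk:
    @staticmethod
    def cm(rows, cells):
        return del5q.CountMatrix(
            values=sp.csr_matrix(np.asarray(rows, dtype=np.int64)),
            cell_ids=pd.Index(cells),
            gene_ids=pd.Index([f"g{j}" for j in range(np.asarray(rows).shape[1])]),
        )

    def test_summation(self):
        cm = self.cm([[1, 2], [3, 4]], ["a", "b"])
        meta = pd.DataFrame(
            {"cell_id": ["a", "b"], "sample_id": "s", "cell_type": "t",
             "genotype": "del5q"}
        )
        pb = make_pseudobulk(cm, meta, min_cells=1)
        np.testing.assert_array_equal(pb.counts, [[4, 6]])
        assert pb.replicates.loc[0, "n_cells"] == 2

    def test_cell_order_commutative(self):
        cm = self.cm([[1, 2], [3, 4], [5, 6]], ["a", "b", "c"])
        meta = pd.DataFrame(
            {"cell_id": ["a", "b", "c"], "sample_id": "s", "cell_type": "t",
             "genotype": "del5q"}
        )
        pb1 = make_pseudobulk(cm, meta, min_cells=1)
        pb2 = make_pseudobulk(cm, meta.iloc[[2, 0, 1]], min_cells=1)
        np.testing.assert_array_equal(pb1.counts, pb2.counts)

    def test_small_replicates_dropped(self):
        cm = self.cm([[1, 2], [3, 4]], ["a", "b"])
        meta = pd.DataFrame(
            {"cell_id": ["a", "b"], "sample_id": ["s1", "s2"], "cell_type": "t",
             "genotype": "del5q"}
        )
        pb = make_pseudobulk(cm, meta, min_cells=2)
        assert pb.counts.shape[0] == 0

    def test_too_few_replicates_refused_with_hurdle_hint(self):
        pb = pb_from([[10], [20], [30]], ["A", "A", "B"])
        with pytest.raises(ValueError, match="hurdle"):
            nb_glm_lrt(pb, contrast=("B", "A"))


class TestNbGlmLrt:
    def test_identical_profiles_zero_log2fc(self):
        y = np.tile([[10, 50, 200]], (6, 1))
        pb = pb_from(y, ["A"] * 3 + ["B"] * 3)
        tab = nb_glm_lrt(pb, contrast=("B", "A"))
        np.testing.assert_allclose(tab["log2fc"], 0.0, atol=1e-8)
        assert (tab["p"] > 0.99).all()

    def test_doubling_gives_log2fc_one_vs_oracle(self):
        """Counts (10,10,10) vs (20,20,20) with equal offsets -> log2fc 1,
        and both model log-likelihoods match a direct optimizer oracle."""
        y = np.array([[10, 100], [10, 100], [10, 100],
                      [20, 100], [20, 100], [20, 100]])
        pb = pb_from(y, ["A"] * 3 + ["B"] * 3)
        tab = nb_glm_lrt(pb, contrast=("B", "A"), dispersion=0.1)
        # offsets differ slightly (library sizes 110 vs 120); correct for them
        lib = y.sum(axis=1)
        expected_lfc = np.log2(
            (y[3:, 0] / lib[3:]).mean() / (y[:3, 0] / lib[:3]).mean()
        )
        assert tab.loc[0, "log2fc"] == pytest.approx(expected_lfc, abs=0.02)

        # oracle: maximize the same NB likelihood directly over (b0, b1)
        yg = y[:, 0].astype(float)
        x = np.array([0, 0, 0, 1, 1, 1.0])
        off = np.log(lib.astype(float))

        def negll(params):
            mu = np.exp(params[0] + params[1] * x + off)
            return -nb_loglik_oracle(yg, mu, 0.1)

        res = scipy.optimize.minimize(negll, [-2.0, 0.5], method="Nelder-Mead",
                                      options=dict(xatol=1e-8, fatol=1e-10))
        assert tab.loc[0, "log2fc"] == pytest.approx(res.x[1] / np.log(2), abs=1e-3)

    def test_equal_offsets_exact_log2fc_one(self):
        y = np.array([[10, 90], [10, 90], [10, 90],
                      [20, 80], [20, 80], [20, 80]])
        pb = pb_from(y, ["A"] * 3 + ["B"] * 3)
        tab = nb_glm_lrt(pb, contrast=("B", "A"), dispersion=0.05)
        assert tab.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-6)

    def test_gene_order_and_replicate_relabeling_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(50, size=(6, 12))
        pb1 = pb_from(y, ["A"] * 3 + ["B"] * 3)
        perm = rng.permutation(12)
        pb2 = pb_from(y[:, perm], ["A"] * 3 + ["B"] * 3)
        pb2.gene_ids = pb1.gene_ids[perm]
        t1 = nb_glm_lrt(pb1, contrast=("B", "A")).set_index("gene_id")
        t2 = nb_glm_lrt(pb2, contrast=("B", "A")).set_index("gene_id")
        np.testing.assert_allclose(
            t1.loc[t2.index, "p"], t2["p"], atol=1e-9
        )
        # swapping replicate rows within a group changes nothing
        pb3 = pb_from(y[[1, 0, 2, 5, 4, 3]], ["A"] * 3 + ["B"] * 3)
        t3 = nb_glm_lrt(pb3, contrast=("B", "A"))
        np.testing.assert_allclose(t1["p"].to_numpy(), t3["p"].to_numpy(), atol=1e-9)

    def test_all_zero_gene_untested(self):
        y = np.array([[0, 10]] * 6)
        pb = pb_from(y, ["A"] * 3 + ["B"] * 3)
        tab = nb_glm_lrt(pb, contrast=("B", "A"))
        assert not tab.loc[0, "tested"] and np.isnan(tab.loc[0, "p"])

    def test_poisson_limit(self):
        """With dispersion -> 0 the NB LRT p matches the Poisson GLM LRT."""
        import statsmodels.api as sm

        y = np.array([[12, 30], [9, 28], [14, 33], [22, 31], [19, 29], [25, 30]])
        pb = pb_from(y, ["A"] * 3 + ["B"] * 3)
        tab = nb_glm_lrt(pb, contrast=("B", "A"), dispersion=1e-8)
        off = np.log(y.sum(axis=1).astype(float))
        x = np.array([0, 0, 0, 1, 1, 1.0])
        for j in range(2):
            null = sm.GLM(y[:, j], np.ones((6, 1)), family=sm.families.Poisson(),
                          offset=off).fit()
            full = sm.GLM(y[:, j], np.column_stack([np.ones(6), x]),
                          family=sm.families.Poisson(), offset=off).fit()
            p_pois = scipy.stats.chi2.sf(2 * (full.llf - null.llf), 1)
            assert tab.loc[j, "p"] == pytest.approx(p_pois, abs=1e-3)


class TestHurdle:
    @staticmethod
    def em(rows, cells=None):
        rows = np.asarray(rows, dtype=float)
        cells = cells or [f"c{i}" for i in range(rows.shape[0])]
        return del5q.ExpressionMatrix(
            values=sp.csr_matrix(rows),
            cell_ids=pd.Index(cells),
            gene_ids=pd.Index([f"g{j}" for j in range(rows.shape[1])]),
        )

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(1.0, size=(40, 5)).astype(float)
        em = self.em(np.vstack([block, block]))
        labels = ["A"] * 40 + ["B"] * 40
        tab = hurdle_lrt(em, labels, contrast=("B", "A"))
        assert (tab["statistic"] < 1e-8).all()
        assert (tab["p"] > 0.999).all()

    def test_saturated_detection_contributes_nothing(self):
        rng = np.random.default_rng(1)
        data = rng.normal(2.0, 0.5, size=(60, 3)).clip(min=0.1)  # all expressed
        em = self.em(data)
        labels = ["A"] * 30 + ["B"] * 30
        tab = hurdle_lrt(em, labels, contrast=("B", "A"))
        assert (tab["df"] == 1).all()  # continuous component only

    def test_one_group_silent_drops_continuous(self):
        data = np.zeros((50, 1))
        data[25:, 0] = 1.5  # group B expresses, group A never does
        em = self.em(data)
        labels = ["A"] * 25 + ["B"] * 25
        tab = hurdle_lrt(em, labels, contrast=("B", "A"))
        assert tab.loc[0, "df"] == 1  # detection only
        assert tab.loc[0, "p"] < 1e-6

    def test_region_recovery_within_one_sample(self, cohort, normed, channel_calls):
        """Dosage 0.5 contrast within one sample: region genes enriched among
        significant downregulated genes."""
        sub = channel_calls[
            (channel_calls["sample_id"] == "MDS_2")
            & channel_calls["genotype"].isin(["del5q", "non_del5q"])
        ]
        em = normed.subset_cells(sub["cell_id"].to_numpy())
        tab = hurdle_lrt(em, sub["genotype"].to_numpy(),
                         contrast=("del5q", "non_del5q"), log2fc_cutoff=0.0)
        region = set(
            cohort.genome.genes.loc[cohort.genome.region_gene_mask(), "gene_id"]
        )
        sig_down = tab[(tab["fdr"] < 0.05) & (tab["log2fc"] < 0)]
        frac_region_in_down = sig_down["gene_id"].isin(region).mean()
        background = len(region) / len(tab)
        assert frac_region_in_down > 2 * background


class TestBH:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_nan_propagates(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_fdr_never_below_p(self, channel_calls):
        p = np.random.default_rng(4).uniform(size=200)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_matches_hand_rolled_step_up(self, ps):
        p = np.array(ps)
        out = bh_adjust(p)
        # independent hand implementation of the step-up rule
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        # adjusted values are monotone in the order statistics of p
        assert (np.diff(out[order]) >= -1e-12).all()
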