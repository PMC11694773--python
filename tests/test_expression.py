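"""Normalisation, NB-LRT differential expression, CV ranking, set scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanomics import (
    CountMatrix,
    CountSimSpec,
    bh_adjust,
    cv_ranking,
    estimate_size_factors,
    filter_low_expression,
    gene_set_score,
    nb_lrt_de,
    simulate_counts,
)
from mechanomics.errors import DesignError, GroupSizeError, NormalizationError


def _cm(counts, sf=None):
    counts = np.asarray(counts)
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(counts.shape[0])],
        [f"b{i}" for i in range(counts.shape[1])],
        size_factors=sf,
    )


class TestSizeFactors:
    def test_exact_proportionality(self):
        a = np.array([[10], [20], [5], [8]])
        cm = _cm(np.hstack([a, 2 * a]))
        out = estimate_size_factors(cm)
        np.testing.assert_allclose(out.size_factors, [2**-0.5, 2**0.5], rtol=1e-12)
        assert np.exp(np.mean(np.log(out.size_factors))) == pytest.approx(1.0)

    def test_identical_spots_all_ones(self):
        a = np.array([[10], [20], [5]])
        cm = _cm(np.hstack([a, a, a]))
        np.testing.assert_allclose(estimate_size_factors(cm).size_factors, 1.0)

    def test_planted_factors_recovered(self):
        labels = np.zeros(3, dtype=object)
        spec = CountSimSpec(
            n_genes=3000, mean_log_mu=np.log(40), mean_log_sigma=0.5,
            dispersion=0.05, size_factor_sigma=0.0, seed=5,
        )
        cm, _ = simulate_counts(labels, spec)
        true = np.array([0.5, 1.0, 2.0])
        true = true / np.exp(np.mean(np.log(true)))
        scaled = np.round(cm.dense() * true[None, :]).astype(int)
        out = estimate_size_factors(_cm(scaled))
        np.testing.assert_allclose(out.size_factors, true, rtol=0.05)

    def test_pooled_variant_recovers_factors(self):
        labels = np.zeros(12, dtype=object)
        spec = CountSimSpec(
            n_genes=2000, mean_log_mu=np.log(30), mean_log_sigma=0.6,
            dispersion=0.05, size_factor_sigma=0.4, seed=6,
        )
        cm, truth = simulate_counts(labels, spec)
        out = estimate_size_factors(cm, method="pooled")
        np.testing.assert_allclose(out.size_factors, truth["size_factors"], rtol=0.1)

    def test_matches_pydeseq2_median_of_ratios(self):
        """Independent oracle: DESeq2-style size factors from pydeseq2."""
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.3, size=(400, 6)) + (
            rng.random((400, 6)) < 0.8
        )
        _, sf_ref = pydeseq2_pp.deseq2_norm(counts.T)  # samples x genes
        cm = estimate_size_factors(_cm(counts))
        sf_ref = sf_ref / np.exp(np.mean(np.log(sf_ref)))
        np.testing.assert_allclose(cm.size_factors, sf_ref, rtol=1e-8)

    def test_no_common_gene_raises(self):
        cm = _cm(np.array([[1, 0], [0, 1]]))
        with pytest.raises(NormalizationError):
            estimate_size_factors(cm)


class TestFilterLowExpression:
    def test_all_zero_gene_ineligible(self):
        cm = _cm(np.vstack([np.zeros(20, int), np.full(20, 5, int)]))
        flags = filter_low_expression(cm)
        assert not flags[0] and flags[1]

    def test_boundary_inclusive(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, 0] = 10  # total exactly 10, detected in 1/20 = 5% of spots
        flags = filter_low_expression(_cm(counts), min_total=10, min_frac_detected=0.05)
        assert flags[0]

    def test_hand_enumeration(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(1.0, size=(10, 40))
        cm = _cm(counts)
        flags = filter_low_expression(cm, min_total=10, min_frac_detected=0.05)
        expected = [
            counts[g].sum() >= 10 and (counts[g] > 0).mean() >= 0.05 for g in range(10)
        ]
        assert flags.tolist() == expected


class TestNbLrtDe:
    labels_40_40 = np.array(["A"] * 40 + ["B"] * 40)

    def test_identical_groups_null_identity(self):
        counts = np.tile(np.array([5, 7, 3, 9, 5] * 8), (3, 2)).reshape(3, 80)
        cm = _cm(counts, sf=np.ones(80))
        res = nb_lrt_de(cm, self.labels_40_40, eligibility=np.ones(3, bool))
        assert res["log2fc"].abs().max() < 1e-6
        assert (res["pvalue"] > 0.9).all()
        assert not res["is_deg"].any()

    def test_null_simulation_call_rate(self):
        spec = CountSimSpec(
            n_genes=2000, mean_log_mu=np.log(50), mean_log_sigma=0.0,
            dispersion=0.1, seed=11,
        )
        cm, _ = simulate_counts(self.labels_40_40, spec)
        res = nb_lrt_de(estimate_size_factors(cm), self.labels_40_40)
        assert res["is_deg"].mean() <= 0.01
        # raw p-values behave: close to uniform at the 5% tail
        assert (res["pvalue"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_planted_effect_recovery(self):
        effects = pd.DataFrame(
            {"gene": np.arange(100), "group": "B", "log2fc": 2.0}
        )
        spec = CountSimSpec(
            n_genes=2000, mean_log_mu=np.log(50), mean_log_sigma=0.0,
            dispersion=0.1, effects=effects, seed=12,
        )
        cm, _ = simulate_counts(self.labels_40_40, spec)
        res = nb_lrt_de(estimate_size_factors(cm), self.labels_40_40)
        planted = res.iloc[:100]
        assert planted["is_deg"].mean() >= 0.8
        assert (planted["log2fc"] - 2.0).abs().median() <= 0.3
        # false-discovery proportion among calls stays controlled
        n_calls = res["is_deg"].sum()
        fdp = res.iloc[100:]["is_deg"].sum() / max(n_calls, 1)
        assert fdp <= 0.1

    def test_dispersion_recovered(self):
        spec = CountSimSpec(
            n_genes=1000, mean_log_mu=np.log(80), mean_log_sigma=0.0,
            dispersion=0.1, seed=13,
        )
        cm, _ = simulate_counts(self.labels_40_40, spec)
        res = nb_lrt_de(estimate_size_factors(cm), self.labels_40_40)
        assert res["dispersion"].median() == pytest.approx(0.1, rel=0.25)

    def test_invariant_to_rescaling_one_spot(self):
        spec = CountSimSpec(
            n_genes=400, mean_log_mu=np.log(30), mean_log_sigma=0.4,
            dispersion=0.08, seed=14,
        )
        labels = np.array(["A"] * 10 + ["B"] * 10)
        cm, _ = simulate_counts(labels, spec)
        res1 = nb_lrt_de(estimate_size_factors(cm), labels)
        counts2 = cm.dense().astype(int)
        counts2[:, 0] *= 3  # triple one spot; factors re-estimated
        res2 = nb_lrt_de(estimate_size_factors(_cm(counts2)), labels)
        ok = res1["converged"] & res2["converged"]
        np.testing.assert_allclose(
            res1.loc[ok, "log2fc"], res2.loc[ok, "log2fc"], atol=0.1
        )
        # p-value ranks essentially preserved
        r1 = res1.loc[ok, "pvalue"].rank()
        r2 = res2.loc[ok, "pvalue"].rank()
        assert r1.corr(r2, method="spearman") > 0.95

    def test_filtered_genes_never_called(self):
        counts = np.vstack([np.zeros(80, int), np.full(80, 20, int)])
        cm = _cm(counts, sf=np.ones(80))
        res = nb_lrt_de(cm, self.labels_40_40)
        assert res.loc[0, "filtered"] and not res.loc[0, "is_deg"]

    def test_small_group_raises(self):
        cm = _cm(np.ones((3, 4), int), sf=np.ones(4))
        with pytest.raises(DesignError):
            nb_lrt_de(cm, np.array(["A", "A", "A", "B"]))

    def test_three_groups_raise(self):
        cm = _cm(np.ones((3, 6), int), sf=np.ones(6))
        with pytest.raises(DesignError):
            nb_lrt_de(cm, np.array(["A", "A", "B", "B", "C", "C"]))


class TestBHAdjust:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 200))
    def test_monotone_and_permutation_invariant(self, seed, n):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, n)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        perm = r.permutation(n)
        np.testing.assert_allclose(bh_adjust(p[perm]), fdr[perm])

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 50)
        n = len(p)
        order = np.argsort(p)
        stepped = p[order] * n / np.arange(1, n + 1)
        oracle = np.minimum.accumulate(stepped[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(oracle, 1.0)
        np.testing.assert_allclose(bh_adjust(p), out)


class TestCvRanking:
    def _region_cm(self, values):
        """values: dict gene -> per-spot normalised counts (sf = 1)."""
        counts = np.array(list(values.values()))
        cm = CountMatrix(
            counts,
            list(values.keys()),
            [f"b{i}" for i in range(counts.shape[1])],
            size_factors=np.ones(counts.shape[1]),
        )
        return cm

    def test_hand_computed_fixture(self):
        cm = self._region_cm(
            {
                "gA": [4, 4, 4, 4],        # cv 0
                "gB": [1, 3, 1, 3],        # mean 2, sd 1.1547, cv 0.5774
                "gC": [2, 2, 2, 6],        # mean 3, sd 2, cv 0.6667
                "gD": [10, 10, 14, 14],    # mean 12, sd 2.3094, cv 0.1925
                "gE": [0, 0, 0, 8],        # detected in 25% only -> excluded
            }
        )
        tab = cv_ranking(cm, cm.barcodes, top_k=None)
        assert tab["gene"].tolist() == ["gA", "gD", "gB", "gC"]
        assert tab["rank"].tolist() == [1, 2, 3, 4]
        np.testing.assert_allclose(
            tab["cv"], [0.0, 2.309401 / 12, 1.154701 / 2, 2.0 / 3], rtol=1e-5
        )

    def test_two_value_sample_sd(self):
        cm = self._region_cm({"g0": [1, 3, 2], "g1": [5, 5, 5]})
        tab = cv_ranking(cm, cm.barcodes, top_k=None)
        assert tab.set_index("gene").loc["g0", "sd"] == pytest.approx(1.0)

    def test_zero_variance_ranks_first(self):
        cm = self._region_cm({"g0": [2, 4, 6], "g1": [5, 5, 5]})
        tab = cv_ranking(cm, cm.barcodes, top_k=None)
        assert tab.loc[0, "gene"] == "g1"

    def test_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, (30, 6))
        cm = _cm(counts, sf=np.ones(6))
        t1 = cv_ranking(cm, cm.barcodes, top_k=None)
        cm2 = _cm(counts * 5, sf=np.ones(6))
        t2 = cv_ranking(cm2, cm2.barcodes, top_k=None)
        assert t1["gene"].tolist() == t2["gene"].tolist()
        np.testing.assert_allclose(t1["cv"], t2["cv"], rtol=1e-12)

    def test_small_region_raises(self):
        cm = self._region_cm({"g0": [1, 2]})
        with pytest.raises(GroupSizeError):
            cv_ranking(cm, cm.barcodes)


class TestGeneSetScore:
    def _two_group_cm(self, n_genes=120, seed=8, shift_genes=(), shift=0.0):
        rng = np.random.default_rng(seed)
        mu = np.full(n_genes, 50.0)
        counts1 = rng.poisson(mu[:, None], (n_genes, 15))
        mu2 = mu.copy()
        mu2[list(shift_genes)] *= 2.0**shift
        counts2 = rng.poisson(mu2[:, None], (n_genes, 15))
        counts = np.hstack([counts1, counts2])
        labels = np.array(["ref"] * 15 + ["high"] * 15)
        return _cm(counts, sf=np.ones(30)), labels

    def test_centered_set_is_null(self):
        cm, labels = self._two_group_cm()
        sets = {"null_set": [f"g{i}" for i in range(0, 40)]}
        res = gene_set_score(cm, labels, sets)
        assert abs(res.loc[0, "stat"]) < 2.5
        assert res.loc[0, "pvalue"] > 0.01

    def test_planted_shift_detected_with_direction(self):
        cm, labels = self._two_group_cm(shift_genes=range(20), shift=1.0)
        res = gene_set_score(
            cm, labels, {"planted": [f"g{i}" for i in range(20)]}
        ).set_index("set")
        assert res.loc["planted", "pvalue"] < 0.01
        # groups in sorted label order: ratios are 'high' relative to 'ref',
        # i.e. log2(ref/high); genes raised in 'high' score negative
        assert res.loc["planted", "direction"] == "down"

    def test_single_gene_set_skipped(self):
        cm, labels = self._two_group_cm()
        with pytest.warns(UserWarning):
            res = gene_set_score(cm, labels, {"tiny": ["g0"], "ok": ["g1", "g2", "g3"]})
        assert res["set"].tolist() == ["ok"]

    def test_permuted_labels_give_uniformish_p(self):
        from scipy import stats as sps

        cm, labels = self._two_group_cm(n_genes=300, seed=9)
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(60):
            perm = rng.permutation(labels)
            sets = {"s": [f"g{i}" for i in rng.choice(300, 25, replace=False)]}
            pvals.append(gene_set_score(cm, perm, sets).loc[0, "pvalue"])
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks <= 0.2
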