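"""Deletion-rate model: training-gene selection, regression, Watterson
conversion and absolutization."""

import numpy as np
import pandas as pd
import pytest

from denovoburden import cnv_rate as cr
from denovoburden import synthetic_data as sd
from denovoburden.genome_io import ConstraintRecord, GeneModel, SDPair, SVSite


def _gene(gene_id, chrom, start, end, autosomal=True, exons=None):
    return GeneModel(
        gene_id,
        chrom,
        "+",
        start,
        end,
        exons=exons or ((start, end),),
        is_autosomal=autosomal,
    )


def _constraint(gene_id, loeuf):
    return ConstraintRecord(gene_id, pli=0.5, loeuf=loeuf, missense_z=0.0)


class TestSelectTrainingGenes:
    def test_intolerant_gene_excluded(self):
        genes = [_gene("a", "chr1", 0, 10_000)]
        sel = cr.select_training_genes(genes, {"a": _constraint("a", 0.20)})
        assert sel == []

    def test_tolerant_isolated_gene_included(self):
        genes = [
            _gene("a", "chr1", 0, 10_000),
            _gene("b", "chr1", 1_600_000, 1_700_000),
        ]
        cons = {"a": _constraint("a", 0.50), "b": _constraint("b", 0.10)}
        # nearest intolerant gene is 1.59 Mb away: outside the 1 Mb flank
        assert cr.select_training_genes(genes, cons) == ["a"]

    def test_intolerant_neighbour_within_flank_excludes(self):
        genes = [
            _gene("a", "chr1", 0, 10_000),
            _gene("b", "chr1", 500_000, 600_000),
        ]
        cons = {"a": _constraint("a", 0.50), "b": _constraint("b", 0.10)}
        assert cr.select_training_genes(genes, cons) == []

    def test_allosomal_gene_excluded(self):
        genes = [_gene("x", "chrX", 0, 10_000, autosomal=False)]
        assert cr.select_training_genes(genes, {"x": _constraint("x", 0.50)}) == []


class TestCountSites:
    genes = [
        _gene("a", "chr1", 1000, 5000),
        _gene("b", "chr1", 5200, 9000),
    ]

    @pytest.mark.parametrize(
        "start,end,expected_total",
        [
            (1000, 1040, 0),  # 40 bp: below the 50 bp floor
            (1000, 2_100_000, 0),  # 2 Mb: above the 1 Mb ceiling
            (1000, 1050, 1),  # exactly 50 bp counts (inclusive bound)
        ],
    )
    def test_size_bounds(self, start, end, expected_total):
        counts = cr.count_lof_cnv_sites([SVSite("chr1", start, end)], self.genes)
        assert counts.sum() == expected_total

    def test_multi_gene_site_counts_for_each(self):
        counts = cr.count_lof_cnv_sites([SVSite("chr1", 4000, 6000)], self.genes)
        assert counts["a"] == 1 and counts["b"] == 1


class TestCovariates:
    chrom_lengths = {"chr1": 100_000_000}

    def test_telomere_distance_capped_at_25mb(self):
        g = _gene("a", "chr1", 30_000_000, 30_100_000)
        cov = cr.compute_covariates(g, [], self.chrom_lengths)
        assert cov["telomere_distance_bp"] == 25_000_000

    def test_gene_at_chromosome_start_has_zero_distance(self):
        g = _gene("a", "chr1", 0, 100_000)
        assert cr.compute_covariates(g, [], self.chrom_lengths)["telomere_distance_bp"] == 0

    def test_no_sd_pairs_gives_zero(self):
        g = _gene("a", "chr1", 0, 100_000)
        assert cr.compute_covariates(g, [], self.chrom_lengths)["n_sd_pairs"] == 0

    def test_nearby_close_pair_counts_distant_pair_does_not(self):
        g = _gene("a", "chr1", 1_000_000, 1_100_000)
        close = SDPair(("chr1", 1_200_000, 1_250_000), ("chr1", 1_500_000, 1_550_000))
        far_apart = SDPair(("chr1", 1_200_000, 1_250_000), ("chr1", 4_000_000, 4_050_000))
        cov = cr.compute_covariates(g, [close, far_apart], self.chrom_lengths)
        assert cov["n_sd_pairs"] == 1

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            cr.compute_covariates(_gene("a", "chr9", 0, 1000), [], self.chrom_lengths)


@pytest.fixture(scope="module")
def fitted(toy_genome, toy_covariates):
    sites, _ = sd.make_sv_catalog(toy_genome, toy_covariates, total_sites=1500, seed=3)
    counts = cr.count_lof_cnv_sites(sites, toy_genome.genes)
    models = cr.fit_cnv_models(counts, toy_covariates)
    return counts, models


class TestModelFitting:
    def test_all_31_subsets_fitted(self, fitted):
        _, models = fitted
        assert len(models) == 31
        assert len({m.covariate_subset for m in models}) == 31

    def test_all_counts_zero_is_error(self, toy_covariates):
        zero = pd.Series(0, index=toy_covariates.index)
        with pytest.raises(ValueError):
            cr.fit_cnv_models(zero, toy_covariates)

    def test_best_model_is_min_aic_with_parsimony_tiebreak(self):
        a = cr.CnvRateModel(("x", "y"), {}, 100.0, 1, "binomial", 10, True)
        b = cr.CnvRateModel(("x",), {}, 90.0, 2, "binomial", 10, True)
        assert cr.select_best_model([a, b]) is b
        tie3 = cr.CnvRateModel(("x", "y", "z"), {}, 90.0, 3, "binomial", 10, True)
        assert cr.select_best_model([a, b, tie3]) is b  # fewer covariates wins the tie

    def test_training_prediction_preserves_total(self, fitted, toy_covariates):
        counts, models = fitted
        best = cr.select_best_model(models)
        predicted = cr.predict_relative_rates(best, toy_covariates.loc[counts.index])
        assert predicted.sum() == pytest.approx(counts.sum(), rel=1e-6)

    def test_identical_covariates_identical_rates(self, fitted, toy_covariates):
        _, models = fitted
        best = cr.select_best_model(models)
        twin = pd.concat([toy_covariates.iloc[[0]], toy_covariates.iloc[[0]]])
        twin.index = ["t1", "t2"]
        rates = cr.predict_relative_rates(best, twin)
        assert rates["t1"] == rates["t2"]

    def test_rate_increases_with_length_under_positive_coefficient(self, fitted, toy_covariates):
        counts, models = fitted
        match = next(m for m in models if m.covariate_subset == ("gene_length_bp",))
        assert match.params["gene_length_bp"] > 0  # generating law is length-increasing
        doubled = toy_covariates.iloc[[0]].copy()
        doubled.index = ["d"]
        doubled["gene_length_bp"] *= 2
        base = cr.predict_relative_rates(match, toy_covariates.iloc[[0]])
        more = cr.predict_relative_rates(match, doubled)
        assert more.iloc[0] > base.iloc[0]

    def test_intercept_only_equivalent_all_genes_equal(self, toy_covariates):
        # constant covariate => all predictions equal the mean count
        rng = np.random.default_rng(0)
        counts = pd.Series(rng.poisson(3, len(toy_covariates)), index=toy_covariates.index)
        covs = toy_covariates.copy()
        covs["gene_length_bp"] = 1.0
        models = cr.fit_cnv_models(counts, covs, covariate_names=("gene_length_bp",))
        rates = cr.predict_relative_rates(models[0], covs)
        assert np.allclose(rates, counts.mean(), rtol=1e-5)


class TestWatterson:
    def test_zero_sites_gives_zero(self):
        assert cr.watterson_total_rate(0, 10, 1000) == 0.0

    def test_hand_computed_closed_form(self):
        # K=4, n=2 => a=1; 4Ne=4 => rate 1.0
        assert cr.watterson_total_rate(4, 2, 1) == pytest.approx(1.0)

    def test_harmonic_factor_via_direct_summation(self):
        # a for n=5 is 1 + 1/2 + 1/3 + 1/4 = 25/12
        a = sum(1.0 / i for i in range(1, 5))
        assert cr.watterson_total_rate(1, 5, 1) == pytest.approx(1.0 / (a * 4))
        assert a == pytest.approx(25 / 12)

    def test_agrees_with_direct_evaluation_on_random_triples(self, rng):
        for _ in range(100):
            K = int(rng.integers(0, 10_000))
            n = int(rng.integers(2, 50_000))
            Ne = int(rng.integers(1, 10**6))
            a = np.sum(1.0 / np.arange(1, n))
            assert cr.watterson_total_rate(K, n, Ne) == pytest.approx(K / (a * 4 * Ne))

    def test_fewer_than_two_alleles_is_error(self):
        with pytest.raises(ValueError):
            cr.watterson_total_rate(1, 1, 1000)

    @pytest.mark.parametrize(
        "rates,expected",
        [([0.001, 0.002], 0.0015), ([0.004], 0.004), ([0.7] * 5, 0.7)],
    )
    def test_population_average(self, rates, expected):
        assert cr.average_population_rates(rates) == pytest.approx(expected)

    def test_empty_population_list_is_error(self):
        with pytest.raises(ValueError):
            cr.average_population_rates([])


class TestAbsolutize:
    def test_reference_constants_reproduce_adjusted_total(self):
        rel = pd.Series({"g": 1824.0})
        absr = cr.absolutize_rates(rel, 0.00155, 1.2, ["g"])
        assert absr["g"] == pytest.approx(0.00186)

    def test_zero_relative_rate_gives_zero(self):
        rel = pd.Series({"t": 10.0, "z": 0.0})
        absr = cr.absolutize_rates(rel, 0.00155, 1.2, ["t"])
        assert absr["z"] == 0.0

    def test_scale_invariance(self):
        rel = pd.Series({"a": 3.0, "b": 7.0, "c": 1.0})
        one = cr.absolutize_rates(rel, 0.001, 1.1, ["a", "b"])
        other = cr.absolutize_rates(rel * 137.0, 0.001, 1.1, ["a", "b"])
        pd.testing.assert_series_equal(one, other)

    def test_training_sum_conservation(self, toy_covariates):
        rel = pd.Series(
            np.random.default_rng(1).uniform(0.1, 5.0, len(toy_covariates)),
            index=toy_covariates.index,
        )
        training = list(rel.index[:40])
        absr = cr.absolutize_rates(rel, 0.00155, 1.2, training)
        assert absr.loc[training].sum() == pytest.approx(0.00155 * 1.2, rel=1e-9)

    def test_zero_training_total_is_error(self):
        with pytest.raises(ValueError):
            cr.absolutize_rates(pd.Series({"a": 0.0}), 0.001, 1.2, ["a"])


class TestGenesPerCnv:
    genes = [
        _gene("a", "chr1", 1000, 5000),
        _gene("b", "chr1", 5200, 9000),
        _gene("c", "chr1", 20_000, 25_000),
    ]

    def test_all_single_gene_sites_give_one(self):
        sites = [SVSite("chr1", 1500, 1600), SVSite("chr1", 21_000, 21_200)]
        assert cr.genes_per_cnv(sites, ["a", "b", "c"], self.genes) == 1.0

    def test_mixed_single_and_double_hit(self):
        sites = [SVSite("chr1", 1500, 1600), SVSite("chr1", 4000, 6000)]
        assert cr.genes_per_cnv(sites, ["a", "b", "c"], self.genes) == 1.5

    def test_matches_brute_force_on_random_catalog(self, toy_genome, toy_covariates, rng):
        sites, _ = sd.make_sv_catalog(toy_genome, toy_covariates, total_sites=100, seed=9)
        training = [g.gene_id for g in toy_genome.genes[:60]]
        got = cr.genes_per_cnv(sites, training, toy_genome.genes)
        # brute force: per-site overlap count over sites hitting >= 1 training gene
        from denovoburden.genome_io import overlaps_exon

        tset = set(training)
        per_site = [
            sum(
                1
                for g in toy_genome.genes
                if g.gene_id in tset and overlaps_exon(s, g)
            )
            for s in sites
            if 50 <= s.size <= 1_000_000
        ]
        per_site = [n for n in per_site if n > 0]
        assert got == pytest.approx(np.mean(per_site))

    def test_no_qualifying_sites_is_error(self):
        with pytest.raises(ValueError):
            cr.genes_per_cnv([SVSite("chr1", 100_000, 100_200)], ["a"], self.genes)


class TestOeRatio:
    def test_elementwise_ratio_and_zero_observed(self):
        obs = pd.Series({"a": 2.0, "b": 0.0})
        exp = pd.Series({"a": 4.0, "b": 5.0})
        ratios = cr.oe_ratio(obs, exp)
        assert ratios["a"] == 0.5 and ratios["b"] == 0.0

    def test_zero_expected_omitted(self):
        obs = pd.Series({"a": 2.0, "b": 1.0})
        exp = pd.Series({"a": 4.0, "b": 0.0})
        assert list(cr.oe_ratio(obs, exp).index) == ["a"]

    def test_neutral_fixture_mean_near_one(self):
        rng = np.random.default_rng(404)
        expected = pd.Series(rng.uniform(1, 20, 400), index=[f"g{i}" for i in range(400)])
        observed = pd.Series(
            rng.poisson(expected.to_numpy()).astype(float), index=expected.index
        )
        ratios = cr.oe_ratio(observed, expected)
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se + 1e-9
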