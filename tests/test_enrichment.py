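"""Poisson burden tests, two-step correction and candidate classification."""

import math

import numpy as np
import pytest

from denovoburden import enrichment as en
from denovoburden import synthetic_data as sd
from denovoburden.genome_io import ConstraintRecord, DnmRecord


def brute_force_poisson_upper(observed, lam, terms=200):
    # term-by-term PMF accumulation, recurrence avoids factorial overflow
    term = math.exp(-lam)
    total = term if observed == 0 else 0.0
    for k in range(1, observed + terms):
        term *= lam / k
        if k >= observed:
            total += term
    return total


class TestElementary:
    def test_expected_count_is_rate_times_trios(self):
        assert en.expected_count(1e-5, 41_165) == pytest.approx(0.41165)
        assert en.expected_count(1e-5, 0) == 0.0
        assert en.expected_count(0.0, 100) == 0.0

    def test_combine_expectations_is_order_invariant_sum(self):
        assert en.combine_expectations([0.1, 0.2]) == pytest.approx(0.3)
        assert en.combine_expectations([0.2, 0.1]) == en.combine_expectations([0.1, 0.2])
        # SNV-LOF plus CNV-LOF means sum into the combined-LOF test mean
        assert en.combine_expectations([0.41, 0.015]) == pytest.approx(0.425)

    def test_poisson_tail_zero_observed_is_one(self):
        assert en.poisson_upper_p(0, 5.0) == 1.0

    def test_poisson_tail_hand_value(self):
        # P(X >= 2 | 0.1) = 1 - e^-0.1 (1 + 0.1)
        assert en.poisson_upper_p(2, 0.1) == pytest.approx(
            1 - math.exp(-0.1) * 1.1, rel=1e-9
        )

    def test_poisson_tail_matches_brute_force(self, rng):
        for _ in range(50):
            lam = float(rng.uniform(0.01, 20))
            obs = int(rng.integers(0, 30))
            assert en.poisson_upper_p(obs, lam) == pytest.approx(
                brute_force_poisson_upper(obs, lam), abs=1e-12
            )

    @pytest.mark.parametrize("n_sig,fdr,expected", [(380, 0.05, 19), (0, 0.05, 0), (100, 0.10, 10)])
    def test_expected_false_positives(self, n_sig, fdr, expected):
        assert en.expected_false_positives(n_sig, fdr) == pytest.approx(expected)

    def test_flat_bonferroni_reference_threshold(self):
        assert en.flat_bonferroni_threshold(20_034) == pytest.approx(8.3e-7, rel=0.01)


class TestRunGeneTests:
    def test_no_observations_gives_unit_pvalues(self):
        gi = en.GeneTestInput("g", lam_lof=0.5, lam_dmis=0.3, obs_lof=0, obs_dmis=0)
        (res,) = en.run_gene_tests([gi])
        assert res.p_lof == 1.0 and res.p_dmis == 1.0 and res.p_combined == 1.0
        assert res.n_tests == 3

    def test_cnv_only_observations_drive_lof_significance(self):
        # a gene whose only signal is de novo CNVs still tests enriched
        gi = en.GeneTestInput("g", lam_lof=0.02, lam_dmis=0.0, obs_lof=3, obs_dmis=0)
        (res,) = en.run_gene_tests([gi])
        assert res.p_lof < 1e-4

    def test_gene_without_mpc_gets_single_test(self):
        gi = en.GeneTestInput("g", 0.5, 0.0, 1, 0, has_mpc=False)
        (res,) = en.run_gene_tests([gi])
        assert res.n_tests == 1 and res.p_dmis is None and res.p_gene == res.p_lof

    def test_spiked_gene_has_smallest_combined_p(self):
        rng = np.random.default_rng(77)
        lams = rng.uniform(0.05, 0.5, 50)
        inputs = []
        for i, lam in enumerate(lams):
            fold = 10.0 if i == 7 else 1.0
            inputs.append(
                en.GeneTestInput(
                    f"g{i}",
                    lam_lof=float(lam),
                    lam_dmis=float(lam) / 2,
                    obs_lof=int(rng.poisson(fold * lam)),
                    obs_dmis=int(rng.poisson(fold * lam / 2)),
                )
            )
        results = en.run_gene_tests(inputs)
        best = min(results, key=lambda r: r.p_combined)
        assert best.gene_id == "g7"

    def test_matching_cnv_signal_never_raises_lof_p(self):
        base = en.GeneTestInput("g", lam_lof=0.2, lam_dmis=0.0, obs_lof=3, obs_dmis=0)
        with_cnv = en.GeneTestInput("g", lam_lof=0.25, lam_dmis=0.0, obs_lof=5, obs_dmis=0)
        (r0,) = en.run_gene_tests([base])
        (r1,) = en.run_gene_tests([with_cnv])
        # observed/lambda ratio grows (15 -> 20): adding the CNV channel helps
        assert r1.p_lof <= r0.p_lof


def bh_stepup(pvals):
    """Independent step-up reference implementation."""
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, pvals[idx] * n / rank)
        q[idx] = prev
    return q


class TestTwoStepAdjust:
    def test_single_gene_single_test(self):
        gi = en.GeneTestInput("g", 0.05, 0.0, 2, 0, has_mpc=False)
        (res,) = en.two_step_adjust(en.run_gene_tests([gi]))
        assert res.p_gene == res.p_lof
        assert res.q == pytest.approx(res.p_gene)

    def test_bh_matches_stepup_oracle(self):
        pvals = [0.01, 0.4, 0.03, 0.0009, 0.2]
        inputs = [
            en.GeneTestInput(f"g{i}", 1.0, 0.0, 0, 0, has_mpc=False) for i in range(5)
        ]
        results = [
            en.EnrichmentResult(f"g{i}", p, None, None, 1, p) for i, p in enumerate(pvals)
        ]
        adjusted = en.two_step_adjust(results)
        expected = bh_stepup(np.array(pvals))
        assert np.allclose([r.q for r in adjusted], expected)

    def test_gene_bonferroni_uses_test_count(self):
        gi = en.GeneTestInput("g", 5.0, 5.0, 11, 0)
        (res,) = en.run_gene_tests([gi])
        assert res.p_gene == pytest.approx(min(1.0, 3 * min(res.p_lof, res.p_dmis, res.p_combined)))

    def test_flat_mode_uses_per_test_threshold(self):
        strong = en.GeneTestInput("hit", 0.01, 0.0, 4, 0, has_mpc=False)  # p ~ 4e-10
        weak = en.GeneTestInput("near", 0.01, 0.0, 2, 0, has_mpc=False)  # p ~ 5e-5
        adjusted = en.two_step_adjust(
            en.run_gene_tests([strong, weak]), mode="flat", n_genes_flat=20_034
        )
        flags = {r.gene_id: r.significant for r in adjusted}
        assert flags["hit"] and not flags["near"]


class TestNullCalibration:
    def test_null_cohort_fdr_controlled(self):
        gene_ids = [f"G{i:04d}" for i in range(200)]
        rates = sd.make_rate_table(gene_ids, seed=3)
        fractions = []
        for s in range(5):
            dnms = sd.make_dnm_cohort(rates, n_trios=20_000, seed=900 + s)
            inputs = en.assemble_inputs({"c": rates}, {"c": 20_000}, dnms)
            res = en.two_step_adjust(en.run_gene_tests(inputs))
            fractions.append(np.mean([r.significant for r in res]))
        assert np.mean(fractions) <= 0.05


def _constraint(gene_id, pli, loeuf, mis_z):
    return ConstraintRecord(gene_id, pli=pli, loeuf=loeuf, missense_z=mis_z)


class TestClassifyCandidates:
    def _result(self, gene, p_lof=1.0, p_dmis=1.0, p_comb=1.0):
        p_gene = min(1.0, 3 * min(p_lof, p_dmis, p_comb))
        return en.EnrichmentResult(gene, p_lof, p_dmis, p_comb, 3, p_gene, q=0.01, significant=True)

    def test_lof_constrained_new_gene_is_plausible(self):
        res = [self._result("g", p_lof=1e-9)]
        cons = {"g": _constraint("g", 0.99, 0.2, 0.0)}
        (call,) = en.classify_candidates(res, [], cons, [])
        assert call.plausible and call.rationale == "lof_constrained"

    def test_recurrent_dmis_new_gene_is_plausible(self):
        res = [self._result("g", p_dmis=1e-9)]
        cons = {"g": _constraint("g", 0.1, 1.0, 1.0)}
        dnms = [
            DnmRecord("s1", "g", "missense", mpc=3.0, amino_acid_position=42),
            DnmRecord("s2", "g", "missense", mpc=2.6, amino_acid_position=42),
        ]
        (call,) = en.classify_candidates(res, [], cons, dnms)
        assert call.plausible and call.rationale == "recurrent_dmis"

    def test_missense_constrained_new_gene_is_plausible(self):
        res = [self._result("g", p_dmis=1e-9)]
        cons = {"g": _constraint("g", 0.1, 1.0, 3.0)}
        (call,) = en.classify_candidates(res, [], cons, [])
        assert call.plausible and call.rationale == "dmis_constrained"

    def test_known_gene_is_not_plausible(self):
        res = [self._result("g", p_lof=1e-9)]
        cons = {"g": _constraint("g", 0.99, 0.2, 0.0)}
        (call,) = en.classify_candidates(res, ["g"], cons, [])
        assert call.status == "known" and not call.plausible

    def test_unconstrained_new_gene_excluded(self):
        res = [self._result("g", p_lof=1e-9)]
        cons = {"g": _constraint("g", 0.1, 1.5, 0.0)}
        (call,) = en.classify_candidates(res, [], cons, [])
        assert call.status == "new" and not call.plausible

    def test_manual_exclusion_list_respected(self):
        res = [self._result("g", p_lof=1e-9)]
        assert en.classify_candidates(res, [], {}, [], exclude=["g"]) == []


class TestLargeCnvFilter:
    def test_calls_above_1mb_discarded(self):
        dnms = [
            DnmRecord("s1", "a", "cnv_lof"),
            DnmRecord("s2", "b", "cnv_lof"),
            DnmRecord("s3", "c", "nonsense"),
        ]
        sizes = {("s1", "a"): 2_000_000, ("s2", "b"): 500_000}
        kept = en.filter_large_dncnvs(dnms, sizes)
        assert [r.sample_id for r in kept] == ["s2", "s3"]
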