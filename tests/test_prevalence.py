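"""Prevalence estimators: the carrier-frequency and couple-sampling
arithmetic, the Bayesian allele-count posterior, averaging, and the
1-in-X display convention."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hfiprev import prevalence as prev
from hfiprev.panel_io import PopulationAFRecord


class TestFormatOneIn:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (61 / 20_919, "1/342"),     # truncation, not rounding (342.93)
            (0.5, "1/2"),
            (1.0, "1/1"),
            (1 / 3, "1/3"),             # float noise must not break exact thirds
        ],
    )
    def test_display(self, p, expected):
        assert prev.format_one_in(p) == expected

    def test_mean_of_three_estimates_truncates(self):
        p = (1 / 470_416 + 1 / 462_233 + 1 / 462_839) / 3  # about 1/465133.5
        assert prev.format_one_in(p) == "1/465133"

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            prev.format_one_in(bad)


class TestCountsAndRatios:
    def test_table_cells_child(self, child_counts):
        assert prev.carrier_frequency(child_counts).display == "1/342"
        assert prev.couple_carrier_risk(child_counts).display == "1/117604"

    def test_table_cells_parent(self, parent_counts):
        assert prev.carrier_frequency(parent_counts).display == "1/371"
        assert prev.couple_carrier_risk(parent_counts).display == "1/138026"

    def test_zero_carriers(self):
        c = prev.CohortCarrierCounts(100, 50, 50, 0, 0)
        assert prev.carrier_frequency(c) == (0.0, "0")
        assert prev.estimate_method1_hw(c).prevalence == 0.0

    def test_carrier_risk_of_one_is_boundary(self):
        c = prev.CohortCarrierCounts(4, 2, 2, 2, 2)
        assert prev.couple_carrier_risk(c).value == 1.0
        assert prev.estimate_method1_hw(c).prevalence == 0.25

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            prev.CohortCarrierCounts(10, 8, 4, 0, 0)  # strata exceed total
        with pytest.raises(ValueError):
            prev.CohortCarrierCounts(10, 5, 5, 6, 0)  # carriers exceed stratum
        with pytest.raises(ValueError):
            prev.CohortCarrierCounts(0, 0, 0, 0, 0)


class TestHWAndCoupleMethods:
    @pytest.mark.parametrize(
        "cohort, m1, m2",
        [("child", "1/470416", "1/462233"), ("parent", "1/552104", "1/571594")],
    )
    def test_printed_estimates(self, cohort, m1, m2, child_counts, parent_counts):
        counts = child_counts if cohort == "child" else parent_counts
        assert prev.estimate_method1_hw(counts).display == m1
        assert prev.estimate_method2_sex_stratified(counts).display == m2

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(1, 10_000), rate_num=st.integers(0, 50),
           rate_den=st.integers(50, 200))
    def test_methods_agree_at_equal_sex_rates(self, n, rate_num, rate_den):
        # both strata carry at rate rate_num/rate_den -> exact identity
        n_male = n_female = n * rate_den
        carriers = n * rate_num
        c = prev.CohortCarrierCounts(
            n_male + n_female, n_male, n_female, carriers, carriers
        )
        e1 = prev.estimate_method1_hw(c).prevalence
        e2 = prev.estimate_method2_sex_stratified(c).prevalence
        assert e2 == pytest.approx(e1, rel=1e-12, abs=0.0)

    def test_couple_enumeration_oracle(self):
        # 6 males (2 carriers) x 6 females (3 carriers): enumerate every
        # couple and every pair of allele transmissions
        male_flags = [1, 1, 0, 0, 0, 0]
        female_flags = [1, 1, 1, 0, 0, 0]
        affected = 0
        trials = 0
        for m, f in itertools.product(male_flags, female_flags):
            for tm, tf in itertools.product([0, 1], repeat=2):
                # a carrier transmits the pathogenic allele on draw 1 of 2
                affected += (m and tm) and (f and tf)
                trials += 1
        oracle = affected / trials
        c = prev.CohortCarrierCounts(12, 6, 6, 2, 3)
        assert prev.estimate_method2_sex_stratified(c).prevalence == pytest.approx(
            oracle, rel=1e-12
        )


class TestBayesianMethod:
    def test_child_point_and_interval(self, child_counts):
        c, n = child_counts.pathogenic_alleles
        est = prev.estimate_method3_bayesian(c, n, seed=0)
        assert 1 / est.prevalence == pytest.approx(462_839, rel=5e-3)
        assert 1 / est.ci_low == pytest.approx(803_692, rel=0.02)
        assert 1 / est.ci_high == pytest.approx(293_567, rel=0.02)

    def test_parent_point(self, parent_counts):
        c, n = parent_counts.pathogenic_alleles
        est = prev.estimate_method3_bayesian(c, n, seed=0)
        assert 1 / est.prevalence == pytest.approx(532_412, rel=5e-3)

    def test_mc_interval_agrees_with_analytic(self):
        est = prev.estimate_method3_bayesian(61, 41_838, mc_samples=200_000, seed=7)
        assert est.mc_ci_low == pytest.approx(est.ci_low, rel=0.05)
        assert est.mc_ci_high == pytest.approx(est.ci_high, rel=0.05)

    @pytest.mark.parametrize("c, n", [(5, 1000), (61, 41_838), (200, 5000)])
    def test_mc_quantiles_match_beta_quantiles(self, c, n):
        # independent oracle: closed-form Beta quantiles squared
        a, b = c + 0.5, n - c + 0.5
        rng = np.random.default_rng(123)
        q = rng.beta(a, b, size=1_000_000)
        mc_lo, mc_hi = np.quantile(q * q, [0.025, 0.975])
        assert mc_lo == pytest.approx(stats.beta.ppf(0.025, a, b) ** 2, rel=0.01)
        assert mc_hi == pytest.approx(stats.beta.ppf(0.975, a, b) ** 2, rel=0.01)
        est = prev.estimate_method3_bayesian(c, n, seed=5, prior="jeffreys",
                                             mc_samples=1_000_000)
        assert est.mc_ci_low == pytest.approx(est.ci_low, rel=0.01)
        assert est.mc_ci_high == pytest.approx(est.ci_high, rel=0.01)

    def test_consistency_with_hardy_weinberg_limit(self):
        # at fixed c/n the posterior point converges to (c/n)^2
        rate = 1e-3
        for n in (10_000, 1_000_000):
            c = int(n * rate)
            est = prev.estimate_method3_bayesian(c, n, seed=0)
            gap = abs(est.prevalence - rate**2) / rate**2
            if n >= 1_000_000:
                assert gap < 1e-3

    def test_all_pathogenic_boundary(self):
        est = prev.estimate_method3_bayesian(500, 500, seed=0, prior="jeffreys")
        assert est.prevalence > 0.99

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            prev.estimate_method3_bayesian(10, 5)
        with pytest.raises(ValueError):
            prev.estimate_method3_bayesian(5, 100, mc_samples=10)
        with pytest.raises(ValueError, match="Haldane"):
            prev.estimate_method3_bayesian(0, 100, prior="haldane")


class TestPopulationAlleleCounts:
    def test_single_variant_matches_hardy_weinberg(self):
        an = 10_000_000
        ac = an // 189
        rec = PopulationAFRecord("A150P", "NFE", ac, an)
        est = prev.estimate_from_population_allele_counts([rec], seed=1)
        assert est.prevalence == pytest.approx((1 / 189) ** 2, rel=1e-3)

    def test_point_is_squared_sum_of_posterior_means(self):
        recs = [
            PopulationAFRecord("V1", "EAS", 40, 100_000),
            PopulationAFRecord("V2", "EAS", 10, 50_000),
        ]
        est = prev.estimate_from_population_allele_counts(recs, seed=1)
        q1 = 40.5 / 100_001
        q2 = 10.5 / 50_001
        assert est.prevalence == pytest.approx((q1 + q2) ** 2, rel=1e-12)

    def test_zero_count_panel_is_prior_driven_and_shrinks_with_an(self):
        points = []
        for an in (10_000, 100_000):
            recs = [PopulationAFRecord(f"V{i}", "EAS", 0, an) for i in range(5)]
            est = prev.estimate_from_population_allele_counts(recs, seed=1)
            expected = (5 * 0.5 / (an + 1)) ** 2
            assert est.prevalence == pytest.approx(expected, rel=1e-12)
            points.append(est.prevalence)
        assert points[1] < points[0]

    def test_mixed_populations_rejected(self):
        recs = [
            PopulationAFRecord("V1", "EAS", 1, 1000),
            PopulationAFRecord("V1", "NFE", 1, 1000),
        ]
        with pytest.raises(ValueError, match="population"):
            prev.estimate_from_population_allele_counts(recs)


class TestAveraging:
    def test_three_identical_estimates(self):
        e = prev.PrevalenceEstimate(method="bayesian", prevalence=1e-6)
        avg = prev.average_estimates([e, e, e])
        assert avg.prevalence == 1e-6
        assert avg.method == "average"

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=8))
    def test_average_bounded_by_inputs(self, probs):
        ests = [prev.PrevalenceEstimate(method="bayesian", prevalence=p)
                for p in probs]
        avg = prev.average_estimates(ests).prevalence
        assert min(probs) <= avg * (1 + 1e-12)
        assert avg <= max(probs) * (1 + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            prev.average_estimates([])


class TestEstimateInvariants:
    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError):
            prev.PrevalenceEstimate(
                method="bayesian", prevalence=0.5, ci_low=0.6, ci_high=0.7
            )

    def test_ci_display_convention(self):
        est = prev.PrevalenceEstimate(
            method="bayesian", prevalence=1 / 462_839,
            ci_low=1 / 803_692, ci_high=1 / 293_567,
        )
        assert est.display == "1/462839"
        assert est.ci_display == "(1/803692 ~ 1/293567)"
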