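"""Exact 2x2 statistics: published values, oracles and invariants."""
import math

import numpy as np
import pytest
from scipy.stats import contingency, fisher_exact, hypergeom

from cpgburden.cohorts import StratumTable
from cpgburden.errors import ConfigurationError, DataIntegrityError
from cpgburden.exact_stats import (
    bonferroni,
    conditional_mle_or,
    exact_ci,
    exact_test,
    fisher_two_sided,
    mantel_haenszel,
    mantel_haenszel_or,
    mantel_haenszel_test,
)

# stratum tables from the published targeted-region analysis
FC_ALL = (5, 849, 6, 2422)
EA_ALL = (12, 3772, 14, 8586)
AA_ALL = (2, 162, 32, 4374)
CPG_STRATA = [(5, 849, 6, 2422), (11, 3773, 9, 8591), (2, 162, 29, 4377)]
FULLGENE_CPG = [(41, 9, 72, 42), (8, 1, 122, 46)]


def _enumeration_p(a, b, c, d):
    """Independent oracle: enumerate every admissible table at fixed margins."""
    m1, m2, k = a + b, c + d, a + c
    lo, hi = max(0, k - m2), min(k, m1)
    if lo == hi:  # single admissible table; scipy's pmf degenerates at N = 0
        return 1.0
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, m1 + m2, m1, k)
    p_obs = probs[a - lo]
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (FC_ALL, 0.17),
            ((1, 853, 0, 2428), 0.26),
            ((1, 853, 1, 2427), 0.45),
            ((2, 852, 5, 2423), 1.00),
            ((1, 285, 5, 2423), 0.50),
        ],
    )
    def test_published_p_values(self, table, expected):
        # published values are printed to 2 decimals; the 0.50 entry appears
        # rounded from a 1-decimal intermediate (exact value 0.4877)
        assert fisher_two_sided(table) == pytest.approx(expected, abs=0.015)

    def test_balanced_table_p_is_one(self):
        assert fisher_two_sided((7, 13, 7, 13)) == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(DataIntegrityError):
            fisher_two_sided((1, -2, 3, 4))

    def test_accepts_stratum_table_and_nested_list(self):
        as_flat = fisher_two_sided(FC_ALL)
        as_nested = fisher_two_sided([[5, 849], [6, 2422]])
        as_table = fisher_two_sided(StratumTable(5, 849, 6, 2422, "FC"))
        assert as_flat == as_nested == as_table

    def test_matches_enumeration_oracle_all_margins(self):
        """Exhaustive sweep over every table with total n <= 30."""
        for m1 in range(0, 31):
            for m2 in range(0, 31 - m1):
                for k in range(0, m1 + m2 + 1):
                    for a in range(max(0, k - m2), min(k, m1) + 1):
                        table = (a, m1 - a, k - a, m2 - (k - a))
                        assert fisher_two_sided(table) == pytest.approx(
                            _enumeration_p(*table), rel=1e-9
                        ), table

    def test_matches_scipy_on_large_tables(self):
        for table in [FC_ALL, EA_ALL, AA_ALL, (41, 9, 72, 42)]:
            a, b, c, d = table
            expected = fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_two_sided(table) == pytest.approx(expected, rel=1e-9)


class TestConditionalMleOr:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (FC_ALL, 2.37),
            (EA_ALL, 1.95),
            ((1, 285, 5, 2423), 1.70),
            ((1, 853, 1, 2427), 2.84),
            ((2, 852, 5, 2423), 1.14),
            ((41, 9, 72, 42), 2.64),
        ],
    )
    def test_published_odds_ratios(self, table, expected):
        # printed to 2 decimals; the 2.37 entry is truncated from 2.3766
        # (the reference implementation prints 2.376588 for that table)
        assert conditional_mle_or(table) == pytest.approx(expected, abs=0.01)

    def test_zero_cells(self):
        assert conditional_mle_or((1, 853, 0, 2428)) == math.inf
        assert conditional_mle_or((0, 854, 3, 2425)) == 0.0
        assert math.isnan(conditional_mle_or((0, 854, 0, 2428)))

    def test_matches_scipy_conditional_estimate(self):
        for table in [FC_ALL, EA_ALL, (41, 9, 72, 42), (3, 17, 8, 12)]:
            a, b, c, d = table
            expected = contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
            assert conditional_mle_or(table) == pytest.approx(
                expected.statistic, rel=1e-6
            )

    def test_strictly_increasing_in_a_at_fixed_margins(self):
        m1, m2, k = 40, 60, 12
        values = [
            conditional_mle_or((a, m1 - a, k - a, m2 - (k - a)))
            for a in range(1, min(k, m1))  # interior of the support
        ]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_sparse_table_approaches_binomial_odds(self):
        """When the variant column is tiny, the MLE nears a/(k-a) * row2/row1."""
        a, k, m1, m2 = 6, 10, 50_000, 100_000
        approx = (a / (k - a)) * (m2 / m1)
        got = conditional_mle_or((a, m1 - a, k - a, m2 - (k - a)))
        assert got == pytest.approx(approx, rel=0.01)

    def test_estimate_lies_inside_its_interval(self):
        for table in [FC_ALL, EA_ALL, AA_ALL, (3, 7, 2, 8), (41, 9, 72, 42)]:
            lower, upper = exact_ci(table)
            assert lower <= conditional_mle_or(table) <= upper


class TestExactCi:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (FC_ALL, (0.6, 9.4)),
            ((1, 853, 0, 2428), (0.1, math.inf)),
            ((1, 853, 1, 2427), (0.0, 223.4)),
            (EA_ALL, (0.8, 4.5)),
        ],
    )
    def test_published_intervals(self, table, expected):
        lower, upper = exact_ci(table)
        assert round(lower, 1) == expected[0]
        if math.isinf(expected[1]):
            assert math.isinf(upper)
        else:
            assert round(upper, 1) == expected[1]

    def test_matches_scipy_interval(self):
        for table in [FC_ALL, (3, 17, 8, 12), (41, 9, 72, 42)]:
            a, b, c, d = table
            expected = contingency.odds_ratio(
                [[a, b], [c, d]], kind="conditional"
            ).confidence_interval(0.95)
            lower, upper = exact_ci(table)
            assert lower == pytest.approx(expected.low, rel=1e-5)
            assert upper == pytest.approx(expected.high, rel=1e-5)

    def test_level_validation(self):
        with pytest.raises(ConfigurationError):
            exact_ci(FC_ALL, level=1.5)

    def test_bundled_result_consistency(self):
        res = exact_test(FC_ALL)
        assert res.p_two_sided == pytest.approx(fisher_two_sided(FC_ALL))
        assert res.or_sample == pytest.approx(5 * 2422 / (849 * 6))


class TestMantelHaenszel:
    def test_published_combined_all_variants(self):
        res = mantel_haenszel([FC_ALL, EA_ALL, AA_ALL])
        assert round(res.or_mh, 2) == 2.00
        assert round(res.ci95[0], 1) == 1.1
        assert round(res.ci95[1], 1) == 3.6
        assert round(res.p, 2) == 0.03
        assert res.chi_sq == pytest.approx(4.77, abs=0.01)

    def test_published_combined_cpg_affecting(self):
        res = mantel_haenszel(CPG_STRATA)
        assert round(res.or_mh, 1) == 2.5
        # reference implementation gives 0.00647 on these printed counts
        assert res.p == pytest.approx(0.006470, abs=1e-5)

    def test_published_fullgene_cpg_split(self):
        res = mantel_haenszel(FULLGENE_CPG)
        assert round(res.or_mh, 2) == 2.71
        assert round(res.ci95[0], 1) == 1.3
        assert round(res.ci95[1], 1) == 5.8
        assert round(res.p, 2) == 0.01

    def test_single_stratum_reduces_to_cross_product(self):
        or_mh, _ = mantel_haenszel_or([(3, 17, 8, 12)])
        assert or_mh == pytest.approx(3 * 12 / (17 * 8))

    def test_identical_strata_equal_single_stratum(self):
        single, _ = mantel_haenszel_or([FC_ALL])
        repeated, _ = mantel_haenszel_or([FC_ALL] * 4)
        assert repeated == pytest.approx(single)

    def test_permutation_invariance(self):
        tables = [FC_ALL, EA_ALL, AA_ALL]
        forward = mantel_haenszel(tables)
        backward = mantel_haenszel(tables[::-1])
        assert forward.or_mh == pytest.approx(backward.or_mh)
        assert forward.p == pytest.approx(backward.p)

    def test_zero_denominator_gives_infinity(self):
        or_mh, ci = mantel_haenszel_or([(3, 17, 0, 20)])
        assert or_mh == math.inf and ci[1] == math.inf

    def test_null_strata_give_zero_chi_square(self):
        # a_i equals its conditional expectation in every stratum
        chi_sq, p = mantel_haenszel_test([(5, 5, 5, 5), (8, 8, 8, 8)])
        assert chi_sq == 0.0 and p == 1.0

    def test_degenerate_strata_rejected(self):
        with pytest.raises(ConfigurationError):
            mantel_haenszel_test([(0, 0, 0, 0)])

    def test_continuity_correction_flag(self):
        with_cc, _ = mantel_haenszel_test([FC_ALL, EA_ALL, AA_ALL], continuity=True)
        without, _ = mantel_haenszel_test([FC_ALL, EA_ALL, AA_ALL], continuity=False)
        assert without > with_cc

    def test_ci_covers_simulated_common_odds_ratio(self):
        """Parameter recovery: RBG interval covers the generating common OR
        in at least 90% of seeded replicates, for null and non-null psi."""
        rng = np.random.default_rng(20240917)
        sizes = [(854, 2428), (3784, 8600), (164, 4406)]
        p_control = 0.002
        for psi in (1.0, 2.5):
            odds = psi * p_control / (1 - p_control)
            p_case = odds / (1 + odds)
            covered = 0
            for _ in range(100):
                tables = []
                for n_case, n_control in sizes:
                    a = rng.binomial(n_case, p_case)
                    c = rng.binomial(n_control, p_control)
                    tables.append((a, n_case - a, c, n_control - c))
                lower, upper = mantel_haenszel_or(tables)[1]
                if (lower if not math.isnan(lower) else 0.0) <= psi <= upper:
                    covered += 1
            assert covered >= 90, f"coverage {covered}/100 at psi={psi}"


class TestBonferroni:
    def test_three_cohort_correction(self):
        assert bonferroni(0.05, 3) == pytest.approx(0.0166667, abs=5e-5)

    def test_single_test_identity(self):
        assert bonferroni(0.05, 1) == 0.05

    @pytest.mark.parametrize("m", [0, -2])
    def test_invalid_m(self, m):
        with pytest.raises(ConfigurationError):
            bonferroni(0.05, m)
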