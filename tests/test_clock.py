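"""Time-dependent dating: scale factors, rounding chain, uncertainty, rates."""

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rhoclock import (
    CoalescenceAgeModel,
    CoalescentPeriodTable,
    FluctuatingSize,
    RateModel,
    compound_poisson_uncertainty,
    decompose_into_periods,
    estimate_age,
    fixation_probability,
    fluctuating_substitution_rate,
    period_age,
    poisson_kyr_uncertainty,
    read_newick_mutation_tree,
    scale_factor,
)
from rhoclock.tree import PeriodRow

from conftest import random_mutation_tree

TABLE = RateModel(rounding_mode="table")
EXACT = RateModel(rounding_mode="exact")


class TestScaleFactor:
    @pytest.mark.parametrize(
        "i,n,exact,table",
        [
            (5, 5, Fraction(1), Fraction(1)),
            (2, 5, Fraction(2, 3), Fraction(67, 100)),
            (3, 5, Fraction(3, 4), Fraction(3, 4)),
            (4, 5, Fraction(4, 5), Fraction(4, 5)),
        ],
    )
    def test_values(self, i, n, exact, table):
        assert scale_factor(i, n, "exact") == exact
        assert scale_factor(i, n, "table") == table

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            scale_factor(1, 5)
        with pytest.raises(ValueError):
            scale_factor(6, 5)

    @given(st.integers(2, 40))
    def test_nondecreasing_and_one_only_at_tip(self, n):
        factors = [scale_factor(i, n, "exact") for i in range(2, n + 1)]
        assert all(a <= b for a, b in zip(factors, factors[1:]))
        assert factors[-1] == 1
        assert all(f < 1 for f in factors[:-1])


class TestPeriodAge:
    @pytest.mark.parametrize(
        "rho,i,scaled_rate,ypm,years",
        [
            (Fraction(3, 2), 2, Fraction(144, 10**6), 6944, 10416),
            (Fraction(2), 3, Fraction(161, 10**6), 6211, 12422),
            (Fraction(1, 2), 4, Fraction(172, 10**6), 5814, 2907),
            (Fraction(1), 5, Fraction(215, 10**6), 4651, 4651),
        ],
    )
    def test_table_mode_rounding_chain(self, rho, i, scaled_rate, ypm, years):
        row = period_age(rho, i, n=5, rate=TABLE)
        assert row.scaled_rate == scaled_rate
        assert row.years_per_mutation == ypm
        assert row.years == years

    def test_exact_mode_tip_period(self):
        row = period_age(Fraction(1), 5, n=5, rate=EXACT)
        assert row.years == 4651

    def test_exact_mode_internal_period(self):
        row = period_age(Fraction(3, 2), 2, n=5, rate=EXACT)
        assert row.years == Fraction(3, 2) * 4651 * Fraction(3, 2)


class TestEstimateAge:
    def test_worked_example_table_mode(self, worked_example_table):
        est = estimate_age(worked_example_table, TABLE)
        assert est.age_years == 30396
        assert est.sd_years == 5513
        assert [int(r.years) for r in est.per_period] == [10416, 12422, 2907, 4651]

    def test_worked_example_exact_mode(self, worked_example_table):
        # term-by-term oracle, no intermediate rounding:
        # 4651 * (3/2 * 3/2 + 2 * 4/3 + 1/2 * 5/4 + 1)
        expected = 4651 * (
            Fraction(3, 2) * Fraction(3, 2)
            + 2 * Fraction(4, 3)
            + Fraction(1, 2) * Fraction(5, 4)
            + 1
        )
        est = estimate_age(worked_example_table, EXACT)
        assert sum(r.years for r in est.per_period) == expected
        # table vs exact totals agree within 0.5%
        assert abs(float(expected) - 30396) / 30396 < 0.005

    def test_star_table_scaling_inert(self):
        # single tip period: age = k * years_per_mutation regardless of mode
        for k in (1, 3, 7):
            table = CoalescentPeriodTable([PeriodRow(index=5, gamma=Fraction(5 * k))])
            assert estimate_age(table, TABLE).age_years == k * 4651
            assert float(estimate_age(table, EXACT).age_years) == k * 4651

    @given(st.integers(0, 10_000), st.integers(3, 9))
    def test_scaled_age_exceeds_unscaled(self, seed, n_tips):
        table = decompose_into_periods(
            random_mutation_tree(random.Random(seed), n_tips)
        )
        scaled = Fraction(
            sum(r.years for r in estimate_age(table, EXACT).per_period)
        )
        unscaled = sum((r.gamma / r.index for r in table.rows), Fraction(0)) * 4651
        internal_mutations = sum(
            (r.gamma for r in table.rows if r.index != table.n), Fraction(0)
        )
        if internal_mutations > 0:
            assert scaled > unscaled
        else:
            assert scaled == unscaled


class TestPoissonKyrUncertainty:
    @pytest.mark.parametrize(
        "age,sd",
        [(30396, 5513), (22277, 4720), (112829, 10622), (165610, 12869), (37701, 6140)],
    )
    def test_reproduces_reference_sds(self, age, sd):
        assert poisson_kyr_uncertainty(age)[0] == sd

    @pytest.mark.parametrize(
        "age,lo,hi",
        [
            (317814, 282873, 352755),
            (165610, 140387, 190833),
            (112829, 92010, 133648),
            (106752, 86501, 127003),
            (37701, 25667, 49735),
        ],
    )
    def test_reproduces_reference_ci_bounds(self, age, lo, hi):
        _, low, high = poisson_kyr_uncertainty(age)
        assert (low, high) == (lo, hi)

    def test_zero_age(self):
        assert poisson_kyr_uncertainty(0) == (0, 0, 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            poisson_kyr_uncertainty(-1)


class TestCompoundPoisson:
    def test_single_period_closed_form(self):
        table = CoalescentPeriodTable([PeriodRow(index=5, gamma=Fraction(5))])
        sd = compound_poisson_uncertainty(table, TABLE)
        assert sd == pytest.approx(math.sqrt(5) * 4651 / 5, rel=1e-12)

    def test_all_zero_gamma(self):
        table = CoalescentPeriodTable(
            [PeriodRow(index=i, gamma=Fraction(0)) for i in (2, 3, 4, 5)]
        )
        assert compound_poisson_uncertainty(table, TABLE) == 0

    def test_monte_carlo_cross_check(self, worked_example_table):
        # resample each gamma_i as Poisson and propagate through the same
        # per-period years-per-mutation; the empirical sd of the total age
        # must match the closed form within 1%
        closed = compound_poisson_uncertainty(worked_example_table, TABLE)
        n = worked_example_table.n
        rng = np.random.default_rng(2024)
        total = np.zeros(100_000)
        for row in worked_example_table.rows:
            ypm_i = float(
                period_age(row.rho(), row.index, n, TABLE).years_per_mutation
            )
            draws = rng.poisson(float(row.gamma), size=total.size)
            total += draws * (ypm_i / row.index)
        assert total.std() == pytest.approx(closed, rel=0.01)


class TestFluctuatingSize:
    def test_fixation_probability_cases(self):
        assert fixation_probability(FluctuatingSize(N0=100, N1=200)) == 2 / 100
        assert fixation_probability(FluctuatingSize(N0=100, N1=50)) == 1 / 200
        assert fixation_probability(FluctuatingSize(N0=100, N1=100)) == 1 / 100

    def test_fixation_probability_clamped(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert fixation_probability(FluctuatingSize(N0=0.5, N1=4)) == 1.0

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            FluctuatingSize(N0=0, N1=1)

    def test_substitution_rate(self):
        mu = 2.15e-4
        assert fluctuating_substitution_rate(
            FluctuatingSize(N0=1, N1=2), mu
        ) == pytest.approx(4.30e-4)
        assert fluctuating_substitution_rate(
            FluctuatingSize(N0=7, N1=7), mu
        ) == pytest.approx(mu)
        assert fluctuating_substitution_rate(
            FluctuatingSize(N0=1, N1=2), mu, backward=True
        ) == pytest.approx(mu / 2)
        with pytest.raises(ValueError):
            fluctuating_substitution_rate(FluctuatingSize(N0=1, N1=2), 0.0)


class TestModelResults:
    def test_from_newick_exact_star(self):
        res = CoalescenceAgeModel.from_newick("(a:2,b:3);").fit(mode="exact")
        assert float(res.age_years) == 2.5 * 4651

    def test_from_period_table_summary(self, worked_example_table):
        res = CoalescenceAgeModel(worked_example_table).fit()
        text = res.summary()
        assert "30,396" in text and "5,513" in text
        frame = res.to_frame()
        assert list(frame["years"]) == [10416, 12422, 2907, 4651]
        assert res.rho_m == 5

    def test_compound_uncertainty_labelled(self, worked_example_table):
        res = CoalescenceAgeModel(worked_example_table).fit(
            uncertainty="compound-poisson"
        )
        assert res.estimate.uncertainty_method == "compound-poisson"
        assert res.sd_years != 5513  # the alternative is not the printed rule
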