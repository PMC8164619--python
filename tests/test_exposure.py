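"""Monte Carlo dose propagation against closed-form lognormal algebra.

With no censoring, no truncation and AF*ED/AT = 1, ln(LADD) is normal with
mean mu_C + mu_IR - mu_BW and variance sigma_C^2 + sigma_IR^2 + sigma_BW^2,
so every simulated percentile has an analytic value and a computable Monte
Carlo standard error — the independent oracle for the simulation path.
"""

import math

import numpy as np
import pytest
from scipy import stats

import dietpra as dp
from dietpra.errors import DomainError, EmptyInputError
from dietpra.synthetic import ConsumptionGroup


def _untruncated_group(label, intake_mean, intake_sd, bw_mean, bw_sd):
    return ConsumptionGroup(
        label=label,
        intake=dp.LognormalSpec(arith_mean=intake_mean, arith_sd=intake_sd),
        bodyweight=dp.LognormalSpec(arith_mean=bw_mean, arith_sd=bw_sd),
    )


class TestDoseEquation:
    def test_median_inputs_hand_arithmetic(self):
        # pooled-survey median concentration x adult-male median intake/BW
        assert dp.compute_ladd(0.028, 121.4, 1.0, 68.5, 1, 1) == pytest.approx(
            0.0496, abs=5e-5
        )

    def test_zero_absorption_annihilates(self):
        assert dp.compute_ladd(0.5, 300.0, 0.0, 60.0, 1, 1) == 0.0

    def test_linearity_in_concentration(self):
        one = dp.compute_ladd(0.04, 150.0, 1.0, 65.0, 1, 1)
        two = dp.compute_ladd(0.08, 150.0, 1.0, 65.0, 1, 1)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nonpositive_bodyweight_rejected(self):
        with pytest.raises(DomainError):
            dp.compute_ladd(0.04, 150.0, 1.0, 0.0, 1, 1)

    def test_hazard_index_identity_and_rounding_consistency(self):
        assert dp.compute_hi(0.36, 0.36) == 1.0
        assert dp.compute_hi(0.0, 0.36) == 0.0
        # an unrounded dose of 0.55 prints as HI 1.5x, not 0.55/0.36 rounded twice
        assert dp.compute_hi(0.55, 0.36) == pytest.approx(1.53, abs=0.01)

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(DomainError):
            dp.compute_hi(0.5, 0.0)


class TestPercentile:
    @pytest.mark.parametrize(
        "values,q,expected",
        [([1, 2, 3, 4, 5], 50, 3.0), ([1, 2, 3, 4], 50, 2.5), ([7], 30, 7.0)],
    )
    def test_linear_interpolation_rule(self, values, q, expected):
        assert dp.percentile(values, q) == expected

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            dp.percentile([], 50)


class TestGroupSimulation:
    def test_point_mass_zero_concentration(self, group_by_label):
        model = dp.ZeroInflatedLognormal(
            p_zero=1.0, positive=dp.LognormalSpec(arith_mean=0.04, arith_sd=0.0)
        )
        s = dp.run_group_simulation(
            model, group_by_label["19-65 years, male"],
            dp.ExposureParams(iterations=5_000, seed=1),
        )
        assert s.ladd_p50 == s.ladd_p95 == 0.0 and s.hi_p95 == 0.0

    def test_same_seed_identical_summaries(self, total_model, group_by_label):
        group = group_by_label["19-65 years, male"]
        params = dp.ExposureParams(iterations=20_000, seed=3)
        assert dp.run_group_simulation(total_model, group, params) == (
            dp.run_group_simulation(total_model, group, params)
        )

    def test_hi_is_ladd_over_rfd_exactly(self, total_model, group_by_label):
        params = dp.ExposureParams(iterations=20_000, seed=4, rfd=0.36)
        s = dp.run_group_simulation(
            total_model, group_by_label["0-3 years, male"], params
        )
        for p in (50, 90, 95):
            ladd = getattr(s, f"ladd_p{p}")
            assert getattr(s, f"hi_p{p}") == pytest.approx(ladd / 0.36, rel=1e-12)

    def test_raising_rfd_scales_hi_down(self, total_model, group_by_label):
        group = group_by_label["19-65 years, male"]
        lo = dp.run_group_simulation(
            total_model, group, dp.ExposureParams(iterations=20_000, seed=5, rfd=0.36)
        )
        hi = dp.run_group_simulation(
            total_model, group, dp.ExposureParams(iterations=20_000, seed=5, rfd=0.72)
        )
        assert hi.hi_p50 == pytest.approx(lo.hi_p50 / 2, rel=1e-12)
        assert hi.hi_p95 == pytest.approx(lo.hi_p95 / 2, rel=1e-12)

    def test_all_groups_shape_and_ordering(self, total_model, groups):
        out = dp.run_all_groups(
            total_model, groups, dp.ExposureParams(iterations=10_000, seed=6)
        )
        assert len(out) == 14
        for s in out:
            assert s.ladd_p50 <= s.ladd_p90 <= s.ladd_p95

    def test_group_order_invariance(self, total_model, groups):
        params = dp.ExposureParams(iterations=10_000, seed=7)
        forward = dp.run_all_groups(total_model, groups, params)
        backward = dp.run_all_groups(total_model, groups[::-1], params)
        assert {s.group: s for s in forward} == {s.group: s for s in backward}

    def test_concentration_scaling_moves_percentiles(self, group_by_label):
        base = dp.ZeroInflatedLognormal(
            p_zero=0.0, positive=dp.LognormalSpec(arith_mean=0.04, arith_sd=0.03)
        )
        tripled = dp.ZeroInflatedLognormal(
            p_zero=0.0, positive=dp.LognormalSpec(arith_mean=0.12, arith_sd=0.09)
        )
        group = group_by_label["19-65 years, male"]
        params = dp.ExposureParams(iterations=50_000, seed=8)
        a = dp.run_group_simulation(base, group, params)
        b = dp.run_group_simulation(tripled, group, params)
        assert b.ladd_p50 == pytest.approx(3 * a.ladd_p50, rel=1e-12)
        assert b.ladd_p95 == pytest.approx(3 * a.ladd_p95, rel=1e-12)


class TestClosedFormOracle:
    def test_simulated_percentiles_match_lognormal_ratio(self):
        """No censoring, no truncation: ln LADD is exactly normal."""
        c = dp.LognormalSpec(arith_mean=0.0449, arith_sd=0.0397)
        group = _untruncated_group("oracle", 171.2, 170.4, 69.33, 11.07)
        model = dp.ZeroInflatedLognormal(p_zero=0.0, positive=c)
        n = 100_000
        params = dp.ExposureParams(iterations=n, seed=9)
        s = dp.run_group_simulation(model, group, params)
        mu = c.mu_log + group.intake.mu_log - group.bodyweight.mu_log
        sigma = math.sqrt(
            c.sigma_log**2 + group.intake.sigma_log**2 + group.bodyweight.sigma_log**2
        )
        for q, got in ((0.50, s.ladd_p50), (0.90, s.ladd_p90), (0.95, s.ladd_p95)):
            expected = math.exp(mu + sigma * stats.norm.ppf(q))
            density = stats.lognorm(sigma, scale=math.exp(mu)).pdf(expected)
            se = math.sqrt(q * (1 - q) / n) / density
            assert abs(got - expected) < 3 * se, q


class TestRegionalTable:
    def test_identical_regions_identical_hi(self, table1, group_by_label):
        (yilan,) = [t for t in table1 if t.region == "Yilan"]
        twin = dp.SurveyTarget(
            region="Yilan", n=yilan.n, mean=yilan.mean, sd=yilan.sd,
            median=yilan.median, max=yilan.max, detect_rate=yilan.detect_rate,
        )
        params = dp.ExposureParams(iterations=10_000, seed=10)
        group = group_by_label["19-65 years, male"]
        a = dp.regional_hi_table([yilan], group, params)
        b = dp.regional_hi_table([twin], group, params)
        assert a == b

    def test_point_mass_region_closed_form_median(self, group_by_label):
        region = dp.SurveyTarget(
            region="flat", n=10, mean=0.05, sd=0.0, median=0.05, max=0.05,
            detect_rate=1.0,
        )
        group = group_by_label["19-65 years, male"]
        n = 100_000
        params = dp.ExposureParams(iterations=n, seed=11, rfd=0.36)
        hi = dp.regional_hi_table([region], group, params)["flat"]
        # C is constant, so median(LADD) = C * median(IR/BW);
        # ln(IR/BW) is normal with the summed parameters
        mu = group.intake.mu_log - group.bodyweight.mu_log
        sigma = math.sqrt(group.intake.sigma_log**2 + group.bodyweight.sigma_log**2)
        expected = 0.05 * math.exp(mu) / 0.36
        density = stats.lognorm(sigma, scale=math.exp(mu)).pdf(math.exp(mu))
        se = 0.05 / 0.36 * math.sqrt(0.25 / n) / density
        assert abs(hi - expected) < 4 * se  # intake truncation adds a hair of bias
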