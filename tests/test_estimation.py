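"""Estimator core: ranges, closed form, draw schemes, Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avert import (
    EstimationConfig,
    FatalityRateModel,
    analytic_mean,
    analytic_quantile,
    draw_rates,
    mc_estimate,
    range_estimate,
)
from avert.estimation import ceil_count, round_half_away, service_draws
from avert.services import UnknownCountError


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(7.7, 8), (3.3, 4), (14.4, 15), (0.3, 1), (0.0, 0), (7.0, 7)]
    )
    def test_ceiling(self, x, expected):
        assert ceil_count(x) == expected

    def test_ceiling_snaps_float_noise(self):
        # 70 * 0.1 is 7.000000000000001 in binary; must not ceil to 8
        assert ceil_count(70 * 0.1) == 7

    @pytest.mark.parametrize(
        "x,expected", [(34.65, 35), (1.35, 1), (12.6, 13), (23.5, 24), (0.4, 0)]
    )
    def test_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestRateModel:
    def test_default_bounds(self, uniform_rate):
        assert (uniform_rate.a, uniform_rate.b) == (0.1, 0.8)
        assert uniform_rate.mean == pytest.approx(0.45)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FatalityRateModel(0.8, 0.1)
        with pytest.raises(ValueError):
            FatalityRateModel(-0.1, 0.5)

    def test_quantile_domain_error(self, uniform_rate):
        with pytest.raises(ValueError):
            uniform_rate.quantile(1.5)


class TestRangeEstimate:
    def test_published_cells(self, uniform_rate, table1_cells):
        for count, (lo, hi), _ in table1_cells:
            est = range_estimate(count, uniform_rate, rounding="ceiling")
            assert (est.lower, est.upper) == (lo, hi), count

    def test_zero_events(self, uniform_rate):
        assert range_estimate(0, uniform_rate).as_tuple() == (0, 0)

    def test_unknown_count_is_explicit_error(self, uniform_rate):
        with pytest.raises(UnknownCountError, match="known_counts"):
            range_estimate(None, uniform_rate)

    def test_rounding_none_returns_products(self, uniform_rate):
        est = range_estimate(299, uniform_rate, rounding="none")
        assert est.lower == pytest.approx(29.9)
        assert est.upper == pytest.approx(239.2)


class TestClosedForm:
    def test_pooled_mean(self, uniform_rate):
        assert analytic_mean(299, uniform_rate) == pytest.approx(134.55)
        assert round_half_away(analytic_mean(299, uniform_rate)) == 135

    def test_service_mean(self, uniform_rate):
        assert analytic_mean(77, uniform_rate) == pytest.approx(34.65)
        assert round_half_away(analytic_mean(77, uniform_rate)) == 35

    def test_zero(self, uniform_rate):
        assert analytic_mean(0, uniform_rate) == 0.0

    def test_pooled_interval_quantiles(self, uniform_rate):
        lo = analytic_quantile(299, uniform_rate, 0.025)
        hi = analytic_quantile(299, uniform_rate, 0.975)
        assert lo == pytest.approx(35.1325)
        assert hi == pytest.approx(233.9675)
        assert (round_half_away(lo), round_half_away(hi)) == (35, 234)

    def test_median_equals_mean_by_symmetry(self, uniform_rate):
        for n in (1, 17, 299):
            assert analytic_quantile(n, uniform_rate, 0.5) == pytest.approx(
                analytic_mean(n, uniform_rate)
            )

    @given(n=st.integers(0, 1000), k=st.integers(1, 7))
    def test_scaling_is_linear_before_rounding(self, n, k):
        model = FatalityRateModel()
        assert analytic_mean(k * n, model) == pytest.approx(k * analytic_mean(n, model))
        raw = range_estimate(n, model, rounding="none")
        raw_k = range_estimate(k * n, model, rounding="none")
        assert raw_k.lower == pytest.approx(k * raw.lower)
        assert raw_k.upper == pytest.approx(k * raw.upper)


class TestDrawRates:
    @pytest.mark.parametrize("scheme", ["midpoint", "stratified", "pseudo"])
    def test_support_and_determinism(self, uniform_rate, scheme):
        r1 = draw_rates(uniform_rate, 10_000, seed=7, scheme=scheme)
        r2 = draw_rates(uniform_rate, 10_000, seed=7, scheme=scheme)
        assert np.array_equal(r1, r2)
        assert r1.min() >= 0.1 and r1.max() <= 0.8

    @pytest.mark.parametrize("scheme", ["midpoint", "stratified", "pseudo"])
    def test_sample_mean_near_uniform_mean(self, uniform_rate, scheme):
        r = draw_rates(uniform_rate, 10_000, seed=11, scheme=scheme)
        assert abs(r.mean() - 0.45) < 0.01  # CLT bound: sd 0.202/sqrt(1e4) ~ 0.002

    def test_pseudo_seed_changes_sequence(self, uniform_rate):
        a = draw_rates(uniform_rate, 100, seed=1, scheme="pseudo")
        b = draw_rates(uniform_rate, 100, seed=2, scheme="pseudo")
        assert not np.array_equal(a, b)

    def test_midpoint_mean_is_exact(self, uniform_rate):
        r = draw_rates(uniform_rate, 10_000, scheme="midpoint")
        assert r.mean() == pytest.approx(0.45, abs=1e-12)

    def test_degenerate_model_collapses(self):
        flat = FatalityRateModel(0.3, 0.3)
        r = draw_rates(flat, 100, scheme="stratified")
        assert np.all(r == pytest.approx(0.3))


class TestMCEstimate:
    def test_reproduces_published_total(self, table1, default_config):
        _, total = mc_estimate(table1.known_counts(), default_config)
        assert (total.point, total.ci_lower, total.ci_upper) == (135, 35, 234)

    def test_reproduces_published_service_cells(self, table1, table1_cells, default_config):
        per, _ = mc_estimate(table1.known_counts(), default_config)
        got = [(r.point, r.ci_lower, r.ci_upper) for r in per.values()]
        assert got == [mc for _, _, mc in table1_cells]

    def test_single_service_count_18(self, default_config):
        per, total = mc_estimate([("DORS", 18)], default_config)
        assert (total.point, total.ci_lower, total.ci_upper) == (8, 2, 14)
        assert per["DORS"] == total

    def test_zero_count_is_exactly_zero(self, default_config):
        _, total = mc_estimate([("empty", 0)], default_config)
        assert (total.point, total.ci_lower, total.ci_upper) == (0, 0, 0)
        assert total.raw_mean == 0.0

    def test_unknown_count_error_directs_to_filter(self, default_config):
        with pytest.raises(UnknownCountError, match="known_counts"):
            mc_estimate([("iKeepr", None)], default_config)

    def test_empty_counts_error(self, default_config):
        with pytest.raises(ValueError, match="empty"):
            mc_estimate([], default_config)

    def test_provenance_recorded(self, default_config):
        _, total = mc_estimate([("A", 10)], default_config)
        assert total.n_draws == 10_000
        assert total.draw_mode == "shared"
        assert total.draw_scheme == "midpoint"
        assert total.seed == default_config.seed

    @pytest.mark.parametrize("scheme", ["midpoint", "stratified", "pseudo"])
    def test_shared_additivity_iteration_by_iteration(self, table1, scheme):
        """Shared-mode total draws equal the per-service sum, draw by draw."""
        config = EstimationConfig(n_draws=2_000, seed=3, draw_scheme=scheme)
        per, total = service_draws(table1.known_counts(), config, FatalityRateModel())
        np.testing.assert_allclose(sum(per.values()), total, rtol=1e-12)

    def test_monotone_in_event_count(self, default_config):
        counts = [(f"s{n}", n) for n in range(0, 200, 7)]
        per, _ = mc_estimate(counts, default_config)
        means = [per[f"s{n}"].raw_mean for n in range(0, 200, 7)]
        los = [per[f"s{n}"].raw_ci[0] for n in range(0, 200, 7)]
        his = [per[f"s{n}"].raw_ci[1] for n in range(0, 200, 7)]
        for seq in (means, los, his):
            assert all(a <= b for a, b in zip(seq, seq[1:]))

    @pytest.mark.parametrize("scheme", ["stratified", "pseudo"])
    def test_independent_total_interval_no_wider_than_shared(self, table1, scheme):
        """Shared draws are comonotone across services, maximising total spread."""
        counts = table1.known_counts()
        shared = EstimationConfig(n_draws=4_000, seed=5, draw_mode="shared", draw_scheme=scheme)
        indep = EstimationConfig(n_draws=4_000, seed=5, draw_mode="independent", draw_scheme=scheme)
        _, t_shared = mc_estimate(counts, shared)
        _, t_indep = mc_estimate(counts, indep)
        shared_width = t_shared.raw_ci[1] - t_shared.raw_ci[0]
        indep_width = t_indep.raw_ci[1] - t_indep.raw_ci[0]
        assert indep_width <= shared_width

    def test_independent_mode_mean_matches_analytic(self, table1):
        config = EstimationConfig(n_draws=10_000, seed=9, draw_mode="independent")
        _, total = mc_estimate(table1.known_counts(), config)
        assert total.raw_mean == pytest.approx(134.55, abs=1.0)

    def test_degenerate_rate_model_collapses_interval(self):
        flat = FatalityRateModel(0.3, 0.3)
        _, total = mc_estimate([("A", 100)], EstimationConfig(), flat)
        assert total.point == total.ci_lower == total.ci_upper == 30

    def test_interval_brackets_point_after_rounding(self, table1):
        for scheme in ("midpoint", "stratified", "pseudo"):
            config = EstimationConfig(n_draws=500, seed=13, draw_scheme=scheme)
            per, total = mc_estimate(table1.known_counts(), config)
            for res in [*per.values(), total]:
                assert res.ci_lower <= res.point <= res.ci_upper
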