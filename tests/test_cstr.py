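"""Tests of CSTR curve fitting, Monte Carlo draws and empirical p-values."""

import numpy as np
import pytest

from pppflux import (
    CSTRFitResult,
    CSTRParams,
    compare_all,
    cstr_model,
    dilution_rate_pvalue,
    fit_cstr,
    monte_carlo_fit,
)
from tests.conftest import TIME_GRID

TRUE = CSTRParams(m_initial=0.01, m_max=0.30, D=0.005)


def _result_from_draws(draws, seed=0):
    draws = np.asarray(draws, dtype=float)
    return CSTRFitResult(
        params=CSTRParams(0.0, 0.5, float(np.mean(draws))),
        residuals=np.zeros(1),
        D_draws=draws,
        n_draws=draws.size,
        converged=np.isfinite(draws),
        seed=seed,
    )


class TestCstrModel:
    def test_value_at_zero_is_m_initial(self):
        assert cstr_model(0.0, TRUE) == pytest.approx(TRUE.m_initial, abs=1e-15)

    def test_asymptote(self):
        assert cstr_model(1e9, TRUE) == pytest.approx(TRUE.m_initial + TRUE.m_max, abs=1e-12)

    def test_zero_rate_is_constant(self):
        flat = CSTRParams(m_initial=0.07, m_max=0.2, D=0.0)
        t = np.array([0.0, 10.0, 900.0, 1e6])
        assert np.allclose(cstr_model(t, flat), 0.07, atol=1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cstr_model(-1.0, TRUE)


class TestFitCstr:
    def test_recovers_noiseless_parameters(self):
        y = cstr_model(TIME_GRID, TRUE)
        fit = fit_cstr(TIME_GRID, y)
        assert fit.params.m_initial == pytest.approx(TRUE.m_initial, rel=1e-6)
        assert fit.params.m_max == pytest.approx(TRUE.m_max, rel=1e-6)
        assert fit.params.D == pytest.approx(TRUE.D, rel=1e-6)
        assert not fit.degenerate

    def test_flat_series_is_degenerate_zero_rate(self):
        fit = fit_cstr(TIME_GRID, np.full(TIME_GRID.size, 0.02))
        assert fit.degenerate
        assert fit.params.D == 0.0
        assert fit.params.m_initial == pytest.approx(0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = cstr_model(TIME_GRID, TRUE) + rng.normal(0, 0.005, TIME_GRID.size)
        order = rng.permutation(TIME_GRID.size)
        a = fit_cstr(TIME_GRID, y)
        b = fit_cstr(TIME_GRID[order], y[order])
        assert a.params == b.params

    def test_too_few_time_points_rejected(self):
        t = np.array([0.0, 10.0, 60.0])
        with pytest.raises(ValueError, match="4 distinct"):
            fit_cstr(t, cstr_model(t, TRUE))

    def test_missing_time_zero_rejected(self):
        t = np.array([10.0, 60.0, 120.0, 240.0])
        with pytest.raises(ValueError, match="t=0"):
            fit_cstr(t, cstr_model(t, TRUE))


class TestMonteCarloFit:
    def _noisy_data(self, sd, seed=11, replicates=3):
        rng = np.random.default_rng(seed)
        t = np.tile(TIME_GRID, replicates)
        return t, cstr_model(t, TRUE) + rng.normal(0, sd, t.size)

    def test_zero_noise_gives_identical_draws(self):
        t = np.tile(TIME_GRID, 2)
        y = cstr_model(t, TRUE)
        result = monte_carlo_fit(t, y, n_draws=25, seed=0, noise_sd=0.0)
        assert np.allclose(result.D_draws, result.D_draws[0], atol=1e-10)
        assert result.D_draws[0] == pytest.approx(TRUE.D, rel=1e-6)

    def test_same_seed_reproduces_draws(self):
        t, y = self._noisy_data(0.01)
        a = monte_carlo_fit(t, y, n_draws=50, seed=9)
        b = monte_carlo_fit(t, y, n_draws=50, seed=9)
        assert np.array_equal(a.D_draws, b.D_draws, equal_nan=True)

    def test_recovers_rate_and_spread_shrinks_with_noise(self):
        t, y = self._noisy_data(0.01)
        loud = monte_carlo_fit(t, y, n_draws=300, seed=4)
        assert np.nanmean(loud.D_draws) == pytest.approx(TRUE.D, rel=0.20)
        t2, y2 = self._noisy_data(0.003)
        quiet = monte_carlo_fit(t2, y2, n_draws=300, seed=4)
        assert np.nanstd(quiet.D_draws) < np.nanstd(loud.D_draws)

    def test_invalid_draw_count_rejected(self):
        t, y = self._noisy_data(0.01)
        with pytest.raises(ValueError, match="n_draws"):
            monte_carlo_fit(t, y, n_draws=0)

    def test_single_replicates_need_explicit_sd(self):
        y = cstr_model(TIME_GRID, TRUE)
        with pytest.raises(ValueError, match="replicates"):
            monte_carlo_fit(TIME_GRID, y, n_draws=10, seed=0)


class TestDilutionRatePvalue:
    def test_printed_formula_extremes(self):
        treatment = _result_from_draws(np.full(1000, 0.001))
        control = _result_from_draws(np.full(1000, 0.005))
        cmp = dilution_rate_pvalue(treatment, control)
        assert cmp.r == 0
        assert cmp.p_empirical == pytest.approx(1 / 1001)
        cmp_rev = dilution_rate_pvalue(control, treatment)
        assert cmp_rev.r == 1000
        assert cmp_rev.p_empirical == 1.0

    def test_floor_never_undershot(self):
        treatment = _result_from_draws(np.linspace(0.001, 0.002, 200))
        control = _result_from_draws(np.linspace(0.004, 0.005, 200))
        cmp = dilution_rate_pvalue(treatment, control)
        assert cmp.p_empirical >= 1 / 201

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.004, 0.0005, 400)
        b = rng.normal(0.005, 0.0005, 400)
        p0 = dilution_rate_pvalue(_result_from_draws(a), _result_from_draws(b)).p_empirical
        p1 = dilution_rate_pvalue(
            _result_from_draws(a + 0.01), _result_from_draws(b + 0.01)
        ).p_empirical
        assert p0 == p1

    def test_mismatched_draw_counts_rejected(self):
        with pytest.raises(ValueError, match="draw counts"):
            dilution_rate_pvalue(
                _result_from_draws(np.ones(10)), _result_from_draws(np.ones(20))
            )

    def test_reverse_direction_flag(self):
        treatment = _result_from_draws(np.full(99, 0.01))
        control = _result_from_draws(np.full(99, 0.005))
        assert dilution_rate_pvalue(treatment, control).p_empirical == 1.0
        assert dilution_rate_pvalue(
            treatment, control, alternative="greater"
        ).p_empirical == pytest.approx(1 / 100)

    def test_null_draws_give_median_p_near_half(self):
        """Same-distribution draw pairs should centre the p-value around 0.5."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            a = _result_from_draws(rng.normal(0.005, 0.0005, 200))
            b = _result_from_draws(rng.normal(0.005, 0.0005, 200))
            ps.append(dilution_rate_pvalue(a, b).p_empirical)
        assert 0.4 < np.median(ps) < 0.6


class TestCompareAll:
    def test_report_row_count_is_conditions_times_targets(self, demo_table):
        result = compare_all(demo_table, "siCon", n_draws=30, seed=0)
        assert len(result.report) == 4 * 2

    def test_control_only_table_has_no_pvalues(self, demo_table):
        sub = demo_table[demo_table.condition == "siCon"]
        result = compare_all(sub, "siCon", n_draws=30, seed=0)
        assert result.report["p_empirical"].isna().all()
        assert result.report["D_hat"].notna().all()

    def test_missing_target_series_reported_not_fatal(self, demo_table):
        result = compare_all(
            demo_table, "siCon", targets=[("Ru5P", 1), ("S7P", 1)], n_draws=30, seed=0
        )
        s7p = result.report[result.report.metabolite == "S7P"]
        assert len(s7p) == 4
        assert s7p["D_hat"].isna().all()
        ru5p = result.report[result.report.metabolite == "Ru5P"]
        assert ru5p["D_hat"].notna().all()

    def test_missing_control_condition_rejected(self, demo_table):
        with pytest.raises(ValueError, match="control"):
            compare_all(demo_table, "siMock", n_draws=10, seed=0)
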