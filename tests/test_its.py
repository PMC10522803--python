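"""Segmented regression: design construction, OLS, Newey-West uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chetrack.errors import DataError, DesignError
from chetrack.its import (
    build_design,
    extrapolate_reference_trend,
    fit_its,
    fit_ols,
    newey_west_se,
)
from chetrack.synthetic import MonthlySimConfig, generate_monthly_use


def segmented_series(n, b1, b2, b3, b4, pos, noise=None):
    """Series generated directly from the regression parameterisation."""
    t = np.arange(1, n + 1)
    m = t - pos
    covid = (t >= pos).astype(float)
    y = b1 + b2 * m + b3 * covid + b4 * covid * m
    if noise is not None:
        y = y + noise
    return y


class TestBuildDesign:
    def test_indicator_switches_at_intervention(self):
        d = build_design(np.linspace(0, 1, 12), intervention_position=4)
        np.testing.assert_array_equal(d.X["covid"], [0, 0, 0] + [1] * 9)

    def test_four_columns_without_year_dummies(self):
        d = build_design(np.linspace(0, 1, 12), 4)
        assert list(d.X.columns) == ["const", "month", "covid", "covid_month"]

    def test_pooled_biennial_design_adds_one_year_dummy(self):
        # two pooled survey years with an extra intercept for the later one
        y = np.concatenate([np.full(12, 0.3), np.full(12, 0.4) + 0.01 * np.arange(12)])
        years = [2018] * 12 + [2020] * 12
        d = build_design(y, 16, year_labels=years, dummy_years=[2020])
        assert d.X.shape[1] == 5 and "year_2020" in d.X.columns

    def test_missing_months_dropped(self):
        y = np.linspace(0, 1, 12)
        y[[2, 7]] = np.nan
        d = build_design(y, 4)
        assert d.y.size == 10
        assert 3 not in d.kept_positions and 8 not in d.kept_positions

    def test_rank_deficiency_raises_design_error(self):
        # a year dummy spanning exactly the post period duplicates the
        # covid indicator
        y = np.linspace(0, 1, 12)
        years = [2019] * 3 + [2020] * 9
        with pytest.raises(DesignError):
            build_design(y, 4, year_labels=years, dummy_years=[2020])

    def test_intervention_outside_series_rejected(self):
        with pytest.raises(DataError):
            build_design(np.linspace(0, 1, 12), 13)


class TestOls:
    def test_noiseless_exact_recovery(self):
        y = segmented_series(24, 1.0, 0.2, -5.0, 0.4, 16)
        res = fit_its(y, 16, lag=1)
        assert res.params["const"] == pytest.approx(1.0, abs=1e-10)
        assert res.params["month"] == pytest.approx(0.2, abs=1e-10)
        assert res.beta3 == pytest.approx(-5.0, abs=1e-10)
        assert res.beta4 == pytest.approx(0.4, abs=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(3)
        y = segmented_series(24, 0.5, 0.1, -2.0, 0.05, 16,
                             noise=rng.normal(0, 0.3, 24))
        d = build_design(y, 16)
        beta, resid = fit_ols(d)
        expected = np.linalg.pinv(d.X.to_numpy()) @ d.y
        np.testing.assert_allclose(beta, expected, atol=1e-10)
        # residuals orthogonal to the design columns
        np.testing.assert_allclose(d.X.to_numpy().T @ resid, 0.0, atol=1e-8)

    def test_flat_series_gives_level_only(self):
        res = fit_its(np.full(18, 0.37), 10, lag=1)
        assert res.params["const"] == pytest.approx(0.37, abs=1e-10)
        for name in ("month", "covid", "covid_month"):
            assert res.params[name] == pytest.approx(0.0, abs=1e-10)


class TestNeweyWest:
    @staticmethod
    def _double_sum_oracle(X, e, lag):
        """Literal Bartlett-weighted double sum, element by element."""
        n, k = X.shape
        S = np.zeros((k, k))
        for t in range(n):
            S += e[t] * e[t] * np.outer(X[t], X[t])
        for j in range(1, lag + 1):
            w = 1.0 - j / (lag + 1.0)
            for t in range(j, n):
                outer = np.outer(X[t], X[t - j])
                S += w * (e[t] * e[t - j] * outer
                          + e[t] * e[t - j] * outer.T)
        xtx_inv = np.linalg.inv(X.T @ X)
        return np.sqrt(np.diag(xtx_inv @ S @ xtx_inv))

    @pytest.fixture
    def small_fit(self):
        rng = np.random.default_rng(21)
        y = segmented_series(20, 0.2, 0.05, -1.0, 0.02, 12,
                             noise=rng.normal(0, 0.2, 20))
        d = build_design(y, 12)
        _, resid = fit_ols(d)
        return d.X.to_numpy(), resid

    def test_lag_zero_equals_hc0(self, small_fit):
        X, resid = small_fit
        se = newey_west_se(X, resid, 0)
        xe = X * resid[:, None]
        bread = np.linalg.inv(X.T @ X)
        hc0 = np.sqrt(np.diag(bread @ (xe.T @ xe) @ bread))
        np.testing.assert_allclose(se, hc0, atol=1e-12)

    def test_lag_two_matches_double_sum_oracle(self, small_fit):
        X, resid = small_fit
        se = newey_west_se(X, resid, 2)
        np.testing.assert_allclose(se, self._double_sum_oracle(X, resid, 2),
                                   atol=1e-10)

    def test_agrees_with_statsmodels_hac(self, small_fit):
        import statsmodels.api as sm

        X, resid = small_fit
        rng = np.random.default_rng(0)
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=X.shape[0])
        res = sm.OLS(y, X).fit(cov_type="HAC",
                               cov_kwds={"maxlags": 3, "use_correction": False})
        se = newey_west_se(X, res.resid, 3)
        np.testing.assert_allclose(se, res.bse, atol=1e-12)

    def test_excessive_lag_rejected(self, small_fit):
        X, resid = small_fit
        with pytest.raises(DataError):
            newey_west_se(X, resid, len(resid))

    def test_long_series_hac_calibrated_against_empirical_sd(self):
        # with i.i.d. noise and a long series, lag-2 NW SEs should sit close
        # to the Monte-Carlo SD of the coefficient estimates
        n, pos = 200, 120
        estimates, ses = [], []
        for r in range(500):
            rng = np.random.default_rng(40_000 + r)
            y = segmented_series(n, 0.3, 0.01, -2.0, 0.0, pos,
                                 noise=rng.normal(0, 1.0, n))
            res = fit_its(y, pos, lag=2)
            estimates.append(res.beta3)
            ses.append(res.nw_se["covid"])
        ratio = np.mean(ses) / np.std(estimates)
        assert 0.85 < ratio < 1.15


class TestFitIts:
    @settings(max_examples=10, deadline=None)
    @given(
        level=st.floats(-0.3, 0.3),
        slope=st.floats(-0.02, 0.02),
        pos=st.integers(6, 18),
    )
    def test_noiseless_generator_recovery(self, level, slope, pos):
        sim = generate_monthly_use(
            MonthlySimConfig(n_months=24, baseline_rate=0.5,
                             seasonal_amplitude=0.0, level_shift=level,
                             slope_shift=slope, intervention_month=pos,
                             noise_sd=0.0)
        )
        if (sim.values == 0).any() or (sim.values == 1).any():
            return  # clamped series no longer follows the linear model
        res = fit_its(sim.values, pos, lag=1)
        assert res.beta3 == pytest.approx(level, abs=1e-8)
        assert res.beta4 == pytest.approx(slope, abs=1e-8)

    def test_constant_offset_moves_only_intercepts(self):
        rng = np.random.default_rng(17)
        y = segmented_series(24, 0.4, 0.02, -1.5, 0.1, 16,
                             noise=rng.normal(0, 0.1, 24))
        a = fit_its(y, 16, lag=1)
        b = fit_its(y + 10.0, 16, lag=1)
        assert b.params["const"] - a.params["const"] == pytest.approx(10.0, abs=1e-8)
        for name in ("month", "covid", "covid_month"):
            assert a.params[name] == pytest.approx(b.params[name], abs=1e-8)

    def test_month_origin_shift_preserves_fitted_values(self):
        # re-origin the month count: fitted values are invariant, only the
        # const / covid coefficients reparameterise
        rng = np.random.default_rng(23)
        y = segmented_series(24, 0.4, 0.02, -1.5, 0.1, 16,
                             noise=rng.normal(0, 0.1, 24))
        d = build_design(y, 16)
        X1 = d.X.to_numpy()
        X2 = X1.copy()
        X2[:, 1] = X1[:, 1] + 7.0  # shifted month origin
        X2[:, 3] = X1[:, 2] * X2[:, 1]
        f1 = X1 @ np.linalg.pinv(X1) @ d.y
        f2 = X2 @ np.linalg.pinv(X2) @ d.y
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_ci_halfwidth_is_z_times_se(self):
        rng = np.random.default_rng(29)
        y = segmented_series(24, 0.4, 0.02, -1.5, 0.1, 16,
                             noise=rng.normal(0, 0.1, 24))
        res = fit_its(y, 16, lag=1)
        np.testing.assert_allclose(
            res.ci95["upper"] - res.params, 1.96 * res.nw_se, atol=1e-12
        )

    def test_type_one_error_of_trend_change_in_balanced_design(self):
        # no true slope change: the beta4 CI should cover zero in >=90% of
        # replicates (balanced pre/post design; truncation matched to the
        # serially independent noise; small-sample t critical values)
        covered = 0
        reps = 500
        for r in range(reps):
            sim = generate_monthly_use(
                MonthlySimConfig(noise_sd=0.02, level_shift=-0.2,
                                 slope_shift=0.0, seasonal_amplitude=0.0,
                                 intervention_month=13, seed=52_000 + r)
            )
            res = fit_its(sim.values, 13, lag=0, use_t=True)
            lo, hi = res.ci95.loc["covid_month"]
            covered += lo <= 0.0 <= hi
        assert covered / reps >= 0.90


class TestExtrapolation:
    def test_constant_reference_extends_constant(self):
        out = extrapolate_reference_trend(np.full(12, 0.25), [13, 14, 24])
        np.testing.assert_allclose(out, 0.25)

    def test_exact_line_continues_exactly(self):
        ref = 0.1 + 0.01 * np.arange(1, 13)
        out = extrapolate_reference_trend(ref, [13, 18])
        np.testing.assert_allclose(out, [0.1 + 0.01 * 13, 0.1 + 0.01 * 18],
                                   atol=1e-12)

    def test_noisy_line_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(31)
        ref = 0.2 + 0.005 * np.arange(1, 13) + rng.normal(0, 0.01, 12)
        pos = np.arange(1, 13, dtype=float)
        X = np.column_stack([np.ones(12), pos])
        a, b = np.linalg.solve(X.T @ X, X.T @ ref)
        out = extrapolate_reference_trend(ref, [15, 20])
        np.testing.assert_allclose(out, [a + b * 15, a + b * 20], atol=1e-10)

    def test_all_missing_reference_rejected(self):
        with pytest.raises(DataError):
            extrapolate_reference_trend(np.full(12, np.nan), [13])
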