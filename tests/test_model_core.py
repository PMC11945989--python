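import numpy as np
import pandas as pd
import pytest

from casim.constrained_fit import SingleIndexRegressor
from casim.model_core import (
    GrowthCurve,
    TimeSeriesDataset,
    WeeklyEffect,
    backfit,
    build_lagged_blocks,
    build_week_design,
    fit_parametric_part,
    growth_curve_value,
    predict,
    CasimRegressor,
)
from casim.simulate import simulate_dataset


def make_dataset(n=60, seed=0, intervention=None, outcome=None):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2001-03-01", periods=n)
    x = np.abs(rng.normal(40, 10, n))
    y = outcome if outcome is not None else np.exp(4 + 0.2 * rng.normal(size=n))
    return TimeSeriesDataset(
        dates=dates,
        outcome=y,
        covariates=pd.DataFrame({"x": x}),
        intervention=intervention,
    )


class TestTimeSeriesDataset:
    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="log transform"):
            make_dataset(outcome=np.zeros(60))

    def test_log_offset_permits_zero(self):
        dates = pd.date_range("2001-03-01", periods=10)
        ds = TimeSeriesDataset(
            dates=dates,
            outcome=np.zeros(10),
            covariates=pd.DataFrame({"x": np.ones(10)}),
            log_offset=0.5,
        )
        np.testing.assert_allclose(ds.log_outcome, np.log(0.5))

    def test_excluded_window_is_open_interval(self):
        ds = make_dataset(intervention=("2001-03-10", "2001-03-20"))
        excl = ds.excluded
        assert not excl[(ds.dates == "2001-03-10").argmax()]
        assert not excl[(ds.dates == "2001-03-20").argmax()]
        assert excl[(ds.dates == "2001-03-15").argmax()]
        assert excl.sum() == 9

    def test_segments_split_at_window(self):
        ds = make_dataset(intervention=("2001-03-10", "2001-03-20"))
        segs = ds.segments()
        assert len(segs) == 2
        assert segs[0].size + segs[1].size + 9 == 60


class TestWeekDesign:
    def test_default_day_row_is_zero(self):
        dates = pd.DatetimeIndex(["2003-03-07"])  # a Friday
        assert dates.day_name()[0] == "Friday"
        assert np.all(build_week_design(dates) == 0)

    def test_single_one_elsewhere(self):
        dates = pd.date_range("2003-03-01", periods=14)
        D = build_week_design(dates)
        fridays = dates.day_name() == "Friday"
        assert np.all(D[fridays].sum(axis=1) == 0)
        assert np.all(D[~fridays].sum(axis=1) == 1)

    def test_fortnight_column_sums(self):
        D = build_week_design(pd.date_range("2003-03-01", periods=14))
        np.testing.assert_array_equal(D.sum(axis=0), np.full(6, 2.0))

    def test_day_order_starts_after_default(self):
        eff = WeeklyEffect(np.arange(6), "Friday")
        assert eff.day_order[0] == "Saturday" and eff.day_order[-1] == "Thursday"


class TestGrowthCurve:
    def setup_method(self):
        self.gc = GrowthCurve(
            np.array([-0.588, 0.010, 0.747, 203.36]),
            pd.Timestamp("2003-03-08"),
            pd.Timestamp("2003-06-23"),
        )

    def test_zero_at_and_before_start(self):
        assert growth_curve_value("2003-03-08", self.gc) == 0.0
        assert growth_curve_value("2001-01-01", self.gc) == 0.0

    def test_midpoint_is_half_rise(self):
        assert self.gc.value_at_tau(203.36) == pytest.approx(-0.588 + 0.747 / 2)

    def test_late_time_asymptote(self):
        assert self.gc.value_at_tau(1e9) == pytest.approx(-0.588 + 0.747, abs=1e-12)

    def test_inside_window_rejected(self):
        with pytest.raises(ValueError):
            growth_curve_value("2003-05-01", self.gc)
        with pytest.raises(ValueError):
            self.gc.value(pd.DatetimeIndex(["2003-05-01"]))


class TestLaggedBlocks:
    def test_lag_zero_equals_column(self):
        ds = make_dataset(n=10)
        used, blocks = build_lagged_blocks(ds, [0])
        np.testing.assert_array_equal(blocks[0][:, 0], ds.covariates["x"].to_numpy())
        assert used.size == 10

    def test_row_counting_with_lag(self):
        ds = make_dataset(n=10)
        used, blocks = build_lagged_blocks(ds, [3])
        assert used.size == 7
        assert blocks[0].shape == (7, 4)
        # row content: current value first, then history
        x = ds.covariates["x"].to_numpy()
        np.testing.assert_array_equal(blocks[0][0], x[3::-1])

    def test_constant_covariate_index_invariant(self):
        dates = pd.date_range("2001-03-01", periods=30)
        ds = TimeSeriesDataset(
            dates=dates,
            outcome=np.full(30, 10.0),
            covariates=pd.DataFrame({"x": np.full(30, 7.0)}),
        )
        _, blocks = build_lagged_blocks(ds, [4])
        assert np.all(blocks[0] == 7.0)

    def test_windows_never_straddle_excluded_period(self):
        ds = make_dataset(intervention=("2001-03-10", "2001-03-20"))
        used, _ = build_lagged_blocks(ds, [5])
        dates_used = ds.dates[used]
        # first 5 rows of each segment are consumed as history
        assert "2001-03-20" not in dates_used.strftime("%Y-%m-%d")
        assert str(dates_used[0].date()) == "2001-03-06"

    def test_infeasible_lag_rejected(self):
        ds = make_dataset(n=10)
        with pytest.raises(ValueError):
            build_lagged_blocks(ds, [10])


class TestParametricPart:
    def test_noiseless_recovery(self):
        n = 600
        dates = pd.date_range("2002-01-01", periods=n)
        window = (pd.Timestamp("2002-08-01"), pd.Timestamp("2002-11-01"))
        mu, alpha = 4.5, np.array([0.07, 0.08, 0.24, 0.16, 0.17, 0.19])
        xi = np.array([-0.6, 0.03, 0.75, 80.0])
        gc = GrowthCurve(xi, *window)
        keep = ~((dates > window[0]) & (dates < window[1]))
        dates_used = dates[keep]
        y = mu + build_week_design(dates_used) @ alpha + gc.value(dates_used)
        ds = TimeSeriesDataset(
            dates=dates,
            outcome=np.ones(n),
            covariates=pd.DataFrame({"x": np.ones(n)}),
            intervention=window,
        )
        mu_h, weekly_h, growth_h, fitted = fit_parametric_part(y, dates_used, ds)
        assert mu_h == pytest.approx(mu, abs=1e-4)
        np.testing.assert_allclose(weekly_h.alpha, alpha, atol=1e-4)
        np.testing.assert_allclose(growth_h.xi, xi, rtol=0.01)
        np.testing.assert_allclose(fitted, y, atol=1e-6)

    def test_pre_intervention_only_reduces_to_dummy_regression(self, rng):
        n = 140
        dates = pd.date_range("2002-01-01", periods=n)
        y = 4.0 + build_week_design(dates) @ np.arange(1, 7) * 0.02 + rng.normal(0, 0.1, n)
        window = (pd.Timestamp("2005-01-01"), pd.Timestamp("2005-05-01"))
        ds = TimeSeriesDataset(
            dates=dates,
            outcome=np.ones(n),
            covariates=pd.DataFrame({"x": np.ones(n)}),
            intervention=window,
        )
        mu_h, weekly_h, growth_h, fitted = fit_parametric_part(y, dates, ds)
        assert np.all(growth_h.xi[[0, 2]] == 0.0)  # zero-effect branch
        D = np.column_stack([np.ones(n), build_week_design(dates)])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert mu_h == pytest.approx(coef[0], abs=1e-10)
        np.testing.assert_allclose(weekly_h.alpha, coef[1:], atol=1e-10)

    def test_constant_response(self):
        n = 400
        dates = pd.date_range("2002-01-01", periods=n)
        window = (pd.Timestamp("2002-05-01"), pd.Timestamp("2002-08-01"))
        keep = ~((dates > window[0]) & (dates < window[1]))
        ds = TimeSeriesDataset(
            dates=dates,
            outcome=np.ones(n),
            covariates=pd.DataFrame({"x": np.ones(n)}),
            intervention=window,
        )
        y = np.full(keep.sum(), 2.5)
        mu_h, weekly_h, growth_h, _ = fit_parametric_part(y, dates[keep], ds)
        assert mu_h == pytest.approx(2.5, abs=1e-10)
        np.testing.assert_allclose(weekly_h.alpha, 0.0, atol=1e-10)
        assert growth_h.xi[2] == 0.0


class TestBackfit:
    def test_degenerate_single_block_matches_spline_fit(self):
        rng = np.random.default_rng(7)
        n = 400
        x = np.abs(rng.normal(50, 15, n))
        y_log = 4.0 + 0.3 * (1 - np.exp(-x / 50))
        ds = TimeSeriesDataset(
            dates=pd.date_range("2000-01-01", periods=n),
            outcome=np.exp(y_log),
            covariates=pd.DataFrame({"x": x}),
        )
        fit = backfit(ds, [0], monotone=[True])
        direct = SingleIndexRegressor(monotone_g=True).fit(x[:, None], y_log)
        assert np.max(np.abs(fit.fitted - direct.predict(x[:, None]))) <= 1e-3
        assert fit.mse <= 1e-5

    def test_rss_trace_non_increasing(self, small_dataset):
        ds, comp = small_dataset
        fit = backfit(ds, comp.truth.lags, monotone=comp.truth.monotone)
        rss = np.asarray(fit.rss_trace)
        assert np.all(np.diff(rss) <= 1e-8 * np.maximum(rss[:-1], 1.0))

    def test_constraints_hold_on_all_blocks(self, small_dataset):
        ds, comp = small_dataset
        fit = backfit(ds, comp.truth.lags, monotone=comp.truth.monotone)
        for w in fit.weights:
            assert abs(w.theta.sum() - 1.0) <= 1e-10
            assert np.all(np.diff(w.theta) <= 1e-12) and w.theta[-1] >= -1e-12
        for g, mono in zip(fit.effects, fit.monotone):
            if mono:
                grid = np.linspace(0, 1, 500)
                assert np.all(np.diff(g.on_unit(grid)) >= -1e-10)

    def test_weekly_zero_on_default_day_and_growth_zero_pre(self, small_dataset):
        ds, comp = small_dataset
        fit = backfit(ds, comp.truth.lags, monotone=comp.truth.monotone)
        fridays = fit.dates_used.day_name() == "Friday"
        assert np.all(fit.weekly.value(fit.dates_used)[fridays] == 0.0)
        pre = fit.dates_used <= fit.growth.t_start
        assert np.all(fit.growth.value(fit.dates_used)[pre] == 0.0)

    def test_effects_centred(self, small_dataset):
        ds, comp = small_dataset
        fit = backfit(ds, comp.truth.lags, monotone=comp.truth.monotone)
        _, blocks = build_lagged_blocks(ds, comp.truth.lags)
        for (w, g), X in zip(fit.blocks, blocks):
            assert abs(np.mean(g(X @ w.theta))) <= 1e-10


class TestPredict:
    def test_identity_on_training_rows(self, small_dataset):
        ds, comp = small_dataset
        fit = backfit(ds, comp.truth.lags, monotone=comp.truth.monotone)
        frame = predict(fit, ds)
        np.testing.assert_allclose(
            frame["log_fitted"] + frame["log_residual"],
            np.log(ds.outcome[fit.used]),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            frame["fitted_original"], np.exp(frame["log_fitted"]), atol=1e-12
        )

    def test_holdout_rmse_matches_recomputation(self, small_truth):
        ds, comp = simulate_dataset(small_truth)
        fit = backfit(ds, small_truth.lags, monotone=small_truth.monotone)
        frame = predict(fit, ds)
        rmse = float(np.sqrt(np.mean(frame["log_residual"] ** 2)))
        manual = float(
            np.sqrt(np.mean((frame["log_observed"] - frame["log_fitted"]) ** 2))
        )
        assert rmse == pytest.approx(manual, abs=1e-14)


class TestCasimRegressorAPI:
    def test_sklearn_conventions(self, small_dataset):
        ds, comp = small_dataset
        X = ds.covariates.set_index(ds.dates)
        est = CasimRegressor(
            lags=comp.truth.lags,
            monotone=comp.truth.monotone,
            intervention=comp.truth.intervention,
        )
        params = est.get_params()
        assert "lags" in params and "intervention" in params
        est.fit(X, ds.outcome)
        assert est.converged_ and est.mse_ > 0
        pred = est.predict(X)
        assert pred.shape[0] == est.fit_.n_used
        assert np.all(pred > 0)  # original-scale counts

    def test_clone_compatible(self, small_dataset):
        from sklearn.base import clone

        ds, comp = small_dataset
        est = CasimRegressor(lags=tuple(comp.truth.lags))
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
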