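"""Full cumulative-effects model and its backfitting estimator.

The model for the log of a daily outcome count is

    ln Y_t = μ + λ(t) + S(t) + Σ_j g_j(θ_jᵀ X_j,t) + ε_t

with μ a constant, S(t) a day-of-week effect (zero on a default day),
λ(t) a four-parameter logistic growth curve capturing a sustained level
shift after an excluded intervention period (zero before it), and one
constrained single-index block per covariate for the cumulative
(distributed-lag) effects.  Estimation alternates a linear/nonlinear
least-squares fit of (μ, α, ξ) with sequential re-estimation of the
single-index blocks on partial residuals until the residual sum of
squares stabilises.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from .constrained_fit import EffectFunction, IndexWeights, SingleIndexRegressor

logger = logging.getLogger(__name__)

WEEK_DAYS = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)
DEFAULT_DAY = "Friday"


# ---------------------------------------------------------------------------
# data containers


@dataclass
class TimeSeriesDataset:
    """Dated outcome counts plus covariate series, with an optional
    excluded intervention window (open interval between the two dates)."""

    dates: pd.DatetimeIndex
    outcome: np.ndarray
    covariates: pd.DataFrame
    intervention: tuple[pd.Timestamp, pd.Timestamp] | None = None
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if len(self.dates) != len(self.outcome) or len(self.dates) != len(self.covariates):
            raise ValueError("dates, outcome and covariates must have equal length")
        if self.dates.has_duplicates:
            dup = self.dates[self.dates.duplicated()][0]
            raise ValueError(f"duplicate date in series: {dup.date()}")
        if not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be sorted increasing")
        if np.any(self.outcome + self.log_offset <= 0):
            bad = self.dates[np.argmax(self.outcome + self.log_offset <= 0)]
            raise ValueError(
                f"non-positive outcome count on {bad.date()}: the log transform "
                "requires positive counts (set log_offset=0.5 to offset zeros)"
            )
        if not np.all(np.isfinite(self.covariates.to_numpy(dtype=float))):
            raise ValueError("covariates contain non-finite values")
        if self.intervention is not None:
            start, end = (pd.Timestamp(d) for d in self.intervention)
            if end <= start:
                raise ValueError("intervention end must follow its start")
            self.intervention = (start, end)

    @property
    def n(self) -> int:
        return len(self.dates)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def log_outcome(self) -> np.ndarray:
        return np.log(self.outcome + self.log_offset)

    @property
    def excluded(self) -> np.ndarray:
        """Rows strictly inside the intervention window (never fitted)."""
        if self.intervention is None:
            return np.zeros(self.n, dtype=bool)
        start, end = self.intervention
        return np.asarray((self.dates > start) & (self.dates < end))

    def segments(self) -> list[np.ndarray]:
        """Runs of consecutive, non-excluded days (positional indices)."""
        keep = np.flatnonzero(~self.excluded)
        if keep.size == 0:
            return []
        gaps = np.flatnonzero(
            (np.diff(self.dates[keep].to_numpy()) != np.timedelta64(1, "D"))
        )
        return np.split(keep, gaps + 1)


@dataclass(frozen=True)
class WeeklyEffect:
    """Day-of-week effects α_1..α_6; exactly zero on the default day.

    Non-default days are indexed in week order starting the day after
    the default day (Friday default ⇒ k = 1..6 is Saturday..Thursday).
    """

    alpha: np.ndarray
    default_day: str = DEFAULT_DAY

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if self.alpha.size != 6:
            raise ValueError("weekly effect needs 6 non-default coefficients")
        if self.default_day not in WEEK_DAYS:
            raise ValueError(f"unknown weekday {self.default_day!r}")

    @property
    def day_order(self) -> tuple[str, ...]:
        i = WEEK_DAYS.index(self.default_day)
        return tuple(WEEK_DAYS[(i + 1 + k) % 7] for k in range(6))

    def value(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return build_week_design(dates, self.default_day) @ self.alpha


@dataclass(frozen=True)
class GrowthCurve:
    """Logistic level shift λ after an excluded intervention window.

    λ(t) = 0 for t ≤ t_start and ξ1 + ξ3 / (1 + exp(−ξ2 (τ − ξ4))) for
    t ≥ t_end, where τ counts days since t_end.
    """

    xi: np.ndarray
    t_start: pd.Timestamp
    t_end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))
        if self.xi.size != 4:
            raise ValueError("growth curve needs 4 parameters")

    def value_at_tau(self, tau) -> np.ndarray:
        x1, x2, x3, x4 = self.xi
        tau = np.asarray(tau, dtype=float)
        out = x1 + x3 * expit(x2 * (tau - x4))
        return out if out.ndim else float(out)

    def value(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Vectorised λ over dates outside the open intervention window."""
        dates = pd.DatetimeIndex(dates)
        inside = (dates > self.t_start) & (dates < self.t_end)
        if inside.any():
            raise ValueError(
                f"growth curve evaluated inside the excluded window at "
                f"{dates[inside][0].date()}"
            )
        tau = (dates - self.t_end).days.to_numpy(dtype=float)
        out = np.zeros(len(dates))
        post = np.asarray(dates >= self.t_end)
        out[post] = self.value_at_tau(tau[post])
        return out


ZERO_XI = np.array([0.0, 0.01, 0.0, 0.0])


def growth_curve_value(t, growth: GrowthCurve) -> float:
    """λ(t) at a single date; raises inside the excluded window."""
    t = pd.Timestamp(t)
    if growth.t_start < t < growth.t_end:
        raise ValueError(f"{t.date()} lies strictly inside the intervention window")
    if t <= growth.t_start:
        return 0.0
    return float(growth.value_at_tau((t - growth.t_end).days))


@dataclass
class CasimFit:
    """Fitted cumulative-effects model on the rows actually used."""

    mu: float
    weekly: WeeklyEffect
    growth: GrowthCurve | None
    lags: np.ndarray
    covariate_names: list[str]
    weights: list[IndexWeights]
    effects: list[EffectFunction]
    monotone: list[bool]
    used: np.ndarray
    dates_used: pd.DatetimeIndex
    fitted: np.ndarray
    residuals: np.ndarray
    mse: float
    aic: float
    n_used: int
    converged: bool
    iterations: int
    rss_trace: list[float] = field(default_factory=list)

    @property
    def blocks(self) -> list[tuple[IndexWeights, EffectFunction]]:
        return list(zip(self.weights, self.effects))

    @property
    def n_parameters(self) -> int:
        return _param_count(self.lags, self.growth is not None)


def _param_count(lags, has_growth: bool) -> int:
    # constant + 6 weekly + 4 growth-curve + free lag weights (sum-to-one
    # removes one per block); spline coefficients excluded (fixed count)
    return 1 + 6 + (4 if has_growth else 0) + int(np.sum(lags))


# ---------------------------------------------------------------------------
# design pieces


def build_week_design(dates: pd.DatetimeIndex, default_day: str = DEFAULT_DAY) -> np.ndarray:
    """n × 6 day-of-week indicators; all-zero row on the default day."""
    dates = pd.DatetimeIndex(dates)
    order = WeeklyEffect(np.zeros(6), default_day).day_order
    col = {day: k for k, day in enumerate(order)}
    design = np.zeros((len(dates), 6))
    for t, name in enumerate(dates.day_name()):
        if name != default_day:
            design[t, col[name]] = 1.0
    return design


def build_lagged_blocks(
    dataset: TimeSeriesDataset, lags, trim: int | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-covariate lagged design blocks on one common row index.

    Row t of block j is (X_j,t, X_j,t−1, …, X_j,t−L_j).  Rows whose
    ``trim``-day history (default: the largest lag) would cross a segment
    boundary or the excluded window are dropped from every block, so all
    blocks share one row index.  Passing a fixed ``trim`` keeps the
    sample identical across candidate lag vectors during lag selection.
    """
    lags = np.asarray(lags, dtype=int)
    if lags.size != len(dataset.covariate_names):
        raise ValueError("one lag per covariate required")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    if trim is None:
        trim = int(lags.max())
    if trim < lags.max():
        raise ValueError("trim must be at least the largest lag")
    used_parts = [seg[trim:] for seg in dataset.segments() if seg.size > trim]
    if not used_parts:
        raise ValueError(
            f"no usable rows: every contiguous segment is shorter than trim={trim} + 1"
        )
    used = np.concatenate(used_parts)
    X = dataset.covariates.to_numpy(dtype=float)
    blocks = []
    for j, L in enumerate(lags):
        cols = [X[used - tau, j] for tau in range(L + 1)]
        blocks.append(np.column_stack(cols))
    return used, blocks


# ---------------------------------------------------------------------------
# parametric part


def _logistic(tau: np.ndarray, xi2: float, xi4: float) -> np.ndarray:
    return expit(xi2 * (tau - xi4))


def fit_parametric_part(
    y_partial: np.ndarray,
    dates_used: pd.DatetimeIndex,
    dataset: TimeSeriesDataset,
    current_growth: GrowthCurve | None = None,
    default_day: str = DEFAULT_DAY,
    week_design: np.ndarray | None = None,
    refine_maxiter: int = 200,
) -> tuple[float, WeeklyEffect, GrowthCurve | None, np.ndarray]:
    """Least-squares fit of μ, weekly α and growth-curve ξ.

    ξ1 and ξ3 enter linearly given (ξ2, ξ4), so the linear block
    (μ, α, ξ1, ξ3) is profiled out by OLS and (ξ2, ξ4) found by a
    multi-start grid plus Nelder–Mead refinement.  Warm-started from
    ``current_growth`` so the parametric objective never increases
    between backfitting sweeps.  Returns (μ, weekly, growth, fitted).
    """
    y = np.asarray(y_partial, dtype=float)
    D = week_design if week_design is not None else build_week_design(dates_used, default_day)
    base = np.column_stack([np.ones(y.size), D])

    def ols(design):
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return coef, float(resid @ resid)

    coef0, rss0 = ols(base)
    window = dataset.intervention
    post = (
        np.asarray(dates_used >= window[1]) if window is not None else np.zeros(y.size, bool)
    )
    if window is None or not post.any():
        if window is not None:
            logger.warning("no post-intervention rows: growth curve fixed at zero effect")
        mu, alpha = float(coef0[0]), coef0[1:7]
        growth = (
            GrowthCurve(ZERO_XI.copy(), *window) if window is not None else None
        )
        return mu, WeeklyEffect(alpha, default_day), growth, base @ coef0

    tau = (dates_used - window[1]).days.to_numpy(dtype=float)

    def profiled(xi2: float, xi4: float):
        lam = np.where(post, 1.0, 0.0)
        curve = np.where(post, _logistic(tau, xi2, xi4), 0.0)
        design = np.column_stack([base, lam, curve])
        return ols(design) + (design,)

    tau_max = float(tau[post].max())
    starts = [(x2, x4) for x2 in (0.005, 0.01, 0.03, 0.1, 0.3) for x4 in np.linspace(
        0.0, max(tau_max, 1.0), 5
    )]
    if current_growth is not None and current_growth.xi[2] != 0.0:
        starts.append((float(current_growth.xi[1]), float(current_growth.xi[3])))
    best = None
    for x2, x4 in starts:
        coef, rss, design = profiled(x2, x4)
        if best is None or rss < best[0]:
            best = (rss, x2, x4)
    _, x2, x4 = best

    def objective(params):
        return profiled(float(np.exp(params[0])), float(params[1]))[1]

    res = minimize(
        objective,
        np.array([np.log(max(x2, 1e-8)), x4]),
        method="Nelder-Mead",
        options={"maxiter": refine_maxiter, "xatol": 1e-8, "fatol": 1e-14},
    )
    x2, x4 = float(np.exp(res.x[0])), float(res.x[1])
    coef, rss, design = profiled(x2, x4)

    if rss0 <= rss + 1e-12 * max(rss0, 1.0):
        # the logistic shift adds nothing (constant or pre-only signal)
        mu, alpha = float(coef0[0]), coef0[1:7]
        return (
            mu,
            WeeklyEffect(alpha, default_day),
            GrowthCurve(ZERO_XI.copy(), *window),
            base @ coef0,
        )
    mu, alpha = float(coef[0]), coef[1:7]
    xi = np.array([coef[7], x2, coef[8], x4])
    return mu, WeeklyEffect(alpha, default_day), GrowthCurve(xi, *window), design @ coef


# ---------------------------------------------------------------------------
# backfitting


def backfit(
    dataset: TimeSeriesDataset,
    lags,
    monotone=None,
    default_day: str = DEFAULT_DAY,
    tol: float = 1e-6,
    max_iter: int = 100,
    si_tol: float = 1e-6,
    si_max_iter: int = 50,
    trim: int | None = None,
    growth_refine_iter: int = 200,
    log_y_override: np.ndarray | None = None,
    init_weights: list[IndexWeights] | None = None,
) -> CasimFit:
    """Two-phase backfitting fit of the full model.

    Phase one initialises the parametric part on the log outcome and the
    single-index blocks sequentially on partial residuals; phase two
    cycles parametric refits and block re-estimations until the relative
    change in RSS drops below ``tol``.  Each fitted g_j is centred to
    sample mean zero over the used rows (offset absorbed into μ) so μ is
    identified.  ``monotone`` flags which covariates get a non-decreasing
    effect curve (default: all).
    """
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    p = len(dataset.covariate_names)
    if monotone is None:
        monotone = [True] * p
    monotone = list(monotone)
    if len(monotone) != p:
        raise ValueError("one monotone flag per covariate required")

    used, blocks_X = build_lagged_blocks(dataset, lags, trim=trim)
    dates_used = dataset.dates[used]
    y = (
        np.asarray(log_y_override, dtype=float)
        if log_y_override is not None
        else dataset.log_outcome[used]
    )
    if y.size != used.size:
        raise ValueError("log-outcome override misaligned with used rows")
    n_used = y.size
    D = build_week_design(dates_used, default_day)

    def parametric(target, growth_prev):
        return fit_parametric_part(
            target,
            dates_used,
            dataset,
            current_growth=growth_prev,
            default_day=default_day,
            week_design=D,
            refine_maxiter=growth_refine_iter,
        )

    mu, weekly, growth, param_fitted = parametric(y, None)
    e = y - param_fitted

    gvals = [np.zeros(n_used) for _ in range(p)]
    weights: list[IndexWeights | None] = list(init_weights) if init_weights else [None] * p
    effects: list[EffectFunction | None] = [None] * p

    def refit_block(j):
        nonlocal mu, e, param_fitted
        Z = e - (sum(gvals) - gvals[j])
        reg = SingleIndexRegressor(
            monotone_g=monotone[j],
            init=weights[j],
            tol=si_tol,
            max_iter=si_max_iter,
        ).fit(blocks_X[j], Z)
        vals = reg.effect_(blocks_X[j] @ reg.weights_.theta)
        offset = float(vals.mean())
        weights[j] = reg.weights_
        effects[j] = reg.effect_.centred(offset)
        gvals[j] = vals - offset
        mu += offset
        param_fitted = param_fitted + offset
        e = e - offset

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for j in range(p):  # Step-3 sequential initialisation
            refit_block(j)
        rss = float(np.sum((e - sum(gvals)) ** 2))
        trace = [rss]
        converged = False
        iterations = 0
        for m in range(1, max_iter + 1):
            iterations = m
            total_g = sum(gvals)
            mu, weekly, growth, param_fitted = parametric(y - total_g, growth)
            e = y - param_fitted
            for j in range(p):
                refit_block(j)
            rss_new = float(np.sum((e - sum(gvals)) ** 2))
            trace.append(rss_new)
            if abs(rss - rss_new) <= tol * max(rss, 1e-300):
                converged = True
                rss = rss_new
                break
            rss = rss_new
    if not converged:
        warnings.warn("backfitting reached max_iter without convergence", stacklevel=2)

    fitted = param_fitted + sum(gvals)
    residuals = y - fitted
    mse = float(np.mean(residuals**2))
    m_params = _param_count(lags, dataset.intervention is not None)
    aic = float(np.log(mse) + 2.0 * m_params / n_used) if mse > 0 else -np.inf
    return CasimFit(
        mu=float(mu),
        weekly=weekly,
        growth=growth,
        lags=lags,
        covariate_names=dataset.covariate_names,
        weights=[w for w in weights],
        effects=[g for g in effects],
        monotone=monotone,
        used=used,
        dates_used=dates_used,
        fitted=fitted,
        residuals=residuals,
        mse=mse,
        aic=aic,
        n_used=n_used,
        converged=converged,
        iterations=iterations,
        rss_trace=trace,
    )


def predict(fit: CasimFit, dataset: TimeSeriesDataset) -> pd.DataFrame:
    """Fitted series on the log and original scales for a dataset.

    Original-scale values are the exponential of the log-scale fit;
    original-scale residuals are observation minus exponentiated fit.
    """
    used, blocks_X = build_lagged_blocks(dataset, fit.lags)
    dates_used = dataset.dates[used]
    log_fit = np.full(used.size, fit.mu)
    log_fit += fit.weekly.value(dates_used)
    if fit.growth is not None:
        log_fit += fit.growth.value(dates_used)
    for (w, g), X in zip(fit.blocks, blocks_X):
        log_fit += g(X @ w.theta)
    obs = dataset.outcome[used]
    return pd.DataFrame(
        {
            "date": dates_used,
            "observed": obs,
            "log_observed": dataset.log_outcome[used],
            "log_fitted": log_fit,
            "log_residual": dataset.log_outcome[used] - log_fit,
            "fitted_original": np.exp(log_fit),
            "residual_original": obs - np.exp(log_fit),
        }
    )


# ---------------------------------------------------------------------------
# estimator front-end


class CasimRegressor(BaseEstimator, RegressorMixin):
    """Cumulative-effects additive single-index regressor.

    scikit-learn-style front end over :func:`backfit`: ``fit`` takes a
    covariate DataFrame indexed by calendar date and the outcome counts,
    ``predict`` returns fitted counts on the original scale.

    Parameters
    ----------
    lags : sequence of int
        Cumulative-lag length per covariate (in column order).
    monotone : sequence of bool, optional
        Non-decreasing effect-curve flag per covariate (pollutant-like
        covariates); default all True.
    intervention : (date, date), optional
        Excluded window; rows strictly inside are never fitted and the
        logistic growth curve switches on at the window's end.
    default_day : str
        Day of week carrying zero weekly effect.
    """

    def __init__(
        self,
        lags=(0,),
        monotone=None,
        intervention=None,
        default_day: str = DEFAULT_DAY,
        tol: float = 1e-6,
        max_iter: int = 100,
        si_tol: float = 1e-6,
        si_max_iter: int = 50,
        log_offset: float = 0.0,
    ):
        self.lags = lags
        self.monotone = monotone
        self.intervention = intervention
        self.default_day = default_day
        self.tol = tol
        self.max_iter = max_iter
        self.si_tol = si_tol
        self.si_max_iter = si_max_iter
        self.log_offset = log_offset

    def _dataset(self, X: pd.DataFrame, y=None) -> TimeSeriesDataset:
        if not isinstance(X, pd.DataFrame) or not isinstance(X.index, pd.DatetimeIndex):
            raise ValueError("X must be a DataFrame indexed by calendar dates")
        outcome = (
            np.asarray(y, dtype=float)
            if y is not None
            else np.ones(len(X))  # prediction only: outcome unused
        )
        return TimeSeriesDataset(
            dates=X.index,
            outcome=outcome,
            covariates=X.reset_index(drop=True),
            intervention=self.intervention,
            log_offset=self.log_offset,
        )

    def fit(self, X: pd.DataFrame, y):
        dataset = self._dataset(X, y)
        fit = backfit(
            dataset,
            self.lags,
            monotone=self.monotone,
            default_day=self.default_day,
            tol=self.tol,
            max_iter=self.max_iter,
            si_tol=self.si_tol,
            si_max_iter=self.si_max_iter,
        )
        self.fit_ = fit
        self.mu_ = fit.mu
        self.alpha_ = fit.weekly.alpha
        self.xi_ = fit.growth.xi if fit.growth is not None else None
        self.weights_ = fit.weights
        self.effects_ = fit.effects
        self.mse_ = fit.mse
        self.aic_ = fit.aic
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        return self

    def predict(self, X: pd.DataFrame):
        frame = predict(self.fit_, self._dataset(X))
        return frame["fitted_original"].to_numpy()

    def predict_frame(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return predict(self.fit_, self._dataset(X, y))
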