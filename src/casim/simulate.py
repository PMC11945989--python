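"""Synthetic daily admission/exposure data with known ground truth.

Emulates the statistical structure the model assumes: positive
autocorrelated exposure series (lognormal AR(1) for pollutant-like
covariates, clipped Gaussian AR(1) for weather-like ones), ordered
non-increasing lag weights, monotone-saturating effect curves for
pollutants and a U-shaped curve for weather, a weekly admission pattern,
a logistic post-intervention level shift, and Gaussian noise on the log
scale.  Counts are the rounded exponential of the log signal.  Every
component series is stored so estimation stages can be scored against
the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .constrained_fit import project_to_ordered_simplex
from .model_core import TimeSeriesDataset, build_week_design

START_DATE = pd.Timestamp("2000-01-01")


def geometric_weights(lag: int, ratio: float = 0.6) -> np.ndarray:
    """Geometric-decay lag weights renormalised onto the ordered simplex."""
    w = ratio ** np.arange(lag + 1)
    return project_to_ordered_simplex(w / w.sum()).theta


@dataclass
class CovariateSpec:
    """Generative description of one exposure series and its effect."""

    name: str
    kind: str  # "pollutant" (monotone-saturating g) or "weather" (U-shaped g)
    lag: int
    mean: float
    sd: float
    rho: float
    theta: np.ndarray | None = None
    # effect-curve parameters (log-outcome units)
    amplitude: float = 0.3
    g_scale: float = 1.0  # saturation scale (pollutant) or U half-width (weather)
    g_center: float = 0.0  # U-shape minimiser (weather only)

    def __post_init__(self) -> None:
        if self.kind not in ("pollutant", "weather"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.theta is None:
            self.theta = geometric_weights(self.lag)
        else:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.size != self.lag + 1:
                raise ValueError("theta must have length lag + 1")

    @property
    def monotone(self) -> bool:
        return self.kind == "pollutant"

    def effect(self, v):
        """True (uncentred) effect curve evaluated at index values v."""
        v = np.asarray(v, dtype=float)
        if self.kind == "pollutant":
            out = self.amplitude * (1.0 - np.exp(-np.maximum(v, 0.0) / self.g_scale))
        else:
            out = self.amplitude * ((v - self.g_center) / self.g_scale) ** 2
        return out if out.ndim else float(out)


@dataclass
class SimulationTruth:
    """Everything needed to generate and to score one synthetic study."""

    n: int = 1500
    covariates: list[CovariateSpec] = field(default_factory=list)
    mu: float = 4.6
    alpha: np.ndarray = field(
        default_factory=lambda: np.array([0.07, 0.08, 0.24, 0.16, 0.17, 0.19])
    )
    xi: np.ndarray = field(default_factory=lambda: np.array([-0.6, 0.01, 0.75, 200.0]))
    window_days: tuple[int, int] | None = None
    default_day: str = "Friday"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def lags(self) -> np.ndarray:
        return np.array([c.lag for c in self.covariates], dtype=int)

    @property
    def monotone(self) -> list[bool]:
        return [c.monotone for c in self.covariates]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(START_DATE, periods=self.n, freq="D")

    @property
    def intervention(self) -> tuple[pd.Timestamp, pd.Timestamp] | None:
        if self.window_days is None:
            return None
        s, e = self.window_days
        return (START_DATE + pd.Timedelta(days=s), START_DATE + pd.Timedelta(days=e))


def default_truth(
    n: int = 1500, noise_sd: float = 0.05, seed: int = 0, lags=(6, 4, 3)
) -> SimulationTruth:
    """Default study conditions: two pollutant-like series and one
    weather-like series at realistic urban scales."""
    specs = [
        CovariateSpec(
            "pm", "pollutant", lags[0], mean=55.0, sd=25.0, rho=0.7,
            amplitude=0.30, g_scale=50.0,
        ),
        CovariateSpec(
            "ox", "pollutant", lags[1], mean=33.0, sd=16.0, rho=0.6,
            amplitude=0.25, g_scale=35.0,
        ),
        CovariateSpec(
            "temp", "weather", lags[2], mean=23.0, sd=5.0, rho=0.85,
            amplitude=0.15, g_scale=5.0, g_center=23.0,
        ),
    ]
    # SARS-like excluded window (~107 days) at 45% of the series, provided the
    # post-intervention stretch is long enough to identify the growth curve
    window = (int(0.45 * n), int(0.45 * n) + 107) if n >= 500 else None
    return SimulationTruth(
        n=n, covariates=specs, noise_sd=noise_sd, seed=seed, window_days=window
    )


def _ar1(rng, n: int, mean: float, sd: float, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = mean + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        z[t] = mean + rho * (z[t - 1] - mean) + innov_sd * eps[t - 1]
    return z


def generate_covariates(
    truth: SimulationTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Stationary positive AR(1)-based daily exposure series."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(2)[0])
    cols = {}
    for spec in truth.covariates:
        if spec.sd == 0:
            cols[spec.name] = np.full(truth.n, spec.mean)
            continue
        if spec.kind == "pollutant":
            # lognormal marginal matched to the requested mean and sd
            sigma2 = np.log(1.0 + (spec.sd / spec.mean) ** 2)
            mu_ln = np.log(spec.mean) - sigma2 / 2.0
            cols[spec.name] = np.exp(_ar1(rng, truth.n, mu_ln, np.sqrt(sigma2), spec.rho))
        else:
            cols[spec.name] = np.maximum(
                _ar1(rng, truth.n, spec.mean, spec.sd, spec.rho), 0.1
            )
    return pd.DataFrame(cols, index=truth.dates)


@dataclass
class SimulationComponents:
    """Per-row truth bookkeeping: the stored components sum exactly to
    the log signal that generated the outcome."""

    truth: SimulationTruth
    log_signal: np.ndarray  # mu + lambda + S + sum g (noise-free)
    lam: np.ndarray
    weekly: np.ndarray
    g_values: list[np.ndarray]  # centred, per covariate
    g_offsets: list[float]
    noise: np.ndarray
    used: np.ndarray  # rows a fit at the true lags would use

    def centred_effect(self, j: int, v):
        return self.truth.covariates[j].effect(v) - self.g_offsets[j]

    def total_log(self) -> np.ndarray:
        return self.log_signal + self.noise


def _lagged_index(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """θ-weighted lag window at every row, padding early history with x[0]."""
    n, L = x.size, theta.size - 1
    padded = np.concatenate([np.full(L, x[0]), x])
    out = np.zeros(n)
    for tau, w in enumerate(theta):
        out += w * padded[L - tau : L - tau + n]
    return out


def generate_response(
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    round_counts: bool = True,
) -> tuple[TimeSeriesDataset, SimulationComponents]:
    """Assemble the outcome series from the truth components.

    The counts are round(exp(log signal + noise)) (rounding optional, for
    exact-recovery tests).  Each true effect curve is centred to mean
    zero over the rows a fit at the true lags would use, so recovered
    parameters are directly comparable with the stored truth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(2)[1])
    n = truth.n
    dates = truth.dates
    if len(covariates) != n:
        raise ValueError("covariate series length differs from truth.n")

    weekly = build_week_design(dates, truth.default_day) @ truth.alpha

    lam = np.zeros(n)
    if truth.intervention is not None:
        _, t_end = truth.intervention
        post = np.asarray(dates >= t_end)
        tau = (dates - t_end).days.to_numpy(dtype=float)
        x1, x2, x3, x4 = truth.xi
        lam[post] = x1 + x3 * expit(x2 * (tau[post] - x4))

    # rows a fit at the true lags would use (depends only on dates/window)
    probe = TimeSeriesDataset(
        dates=dates,
        outcome=np.ones(n),
        covariates=covariates.reset_index(drop=True),
        intervention=truth.intervention,
    )
    trim = int(truth.lags.max()) if len(truth.covariates) else 0
    used = np.concatenate(
        [seg[trim:] for seg in probe.segments() if seg.size > trim]
    )

    g_values, g_offsets = [], []
    for spec in truth.covariates:
        idx = _lagged_index(covariates[spec.name].to_numpy(dtype=float), spec.theta)
        raw = spec.effect(idx)
        offset = float(raw[used].mean())
        g_values.append(raw - offset)
        g_offsets.append(offset)

    log_signal = truth.mu + lam + weekly + sum(g_values, np.zeros(n))
    noise = truth.noise_sd * rng.standard_normal(n)
    target = np.exp(log_signal + noise)
    if np.any(~np.isfinite(target)):
        raise OverflowError("log signal overflows the exponential")
    outcome = np.maximum(np.round(target), 1.0) if round_counts else target

    dataset = TimeSeriesDataset(
        dates=dates,
        outcome=outcome,
        covariates=covariates.reset_index(drop=True),
        intervention=truth.intervention,
    )
    components = SimulationComponents(
        truth=truth,
        log_signal=log_signal,
        lam=lam,
        weekly=weekly,
        g_values=g_values,
        g_offsets=g_offsets,
        noise=noise,
        used=used,
    )
    return dataset, components


def simulate_dataset(
    truth: SimulationTruth, round_counts: bool = True
) -> tuple[TimeSeriesDataset, SimulationComponents]:
    """Generate covariates and response in one deterministic call."""
    seqs = np.random.SeedSequence(truth.seed).spawn(2)
    covs = generate_covariates(truth, np.random.default_rng(seqs[0]))
    return generate_response(
        covs, truth, np.random.default_rng(seqs[1]), round_counts=round_counts
    )
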