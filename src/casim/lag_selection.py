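"""AIC-based search for (locally) optimal cumulative-lag lengths.

The search first scans a coarse common-lag grid (all L_j equal), then
refines one coordinate at a time over a ±d window until a full cycle
leaves every lag unchanged.  All candidate fits during the search share
one row sample (trimmed by the global bound K) so their AIC values are
comparable; because the sample size is then fixed, AIC reduces to
log MSE + 2m/n with m the free-parameter count (spline coefficients
excluded: their number does not vary with the lags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model_core import CasimFit, TimeSeriesDataset, _param_count, backfit

logger = logging.getLogger(__name__)

# search fits favour speed over final polish; the selected model is
# refit at full settings afterwards
SEARCH_FIT_DEFAULTS = dict(max_iter=12, si_max_iter=25, growth_refine_iter=60)


@dataclass(frozen=True)
class LagStructure:
    """Per-covariate cumulative-lag lengths with their upper bound."""

    lags: np.ndarray
    K: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        object.__setattr__(self, "lags", lags)
        if np.any(lags < 0) or np.any(lags > self.K):
            raise ValueError(f"lags must lie in [0, K={self.K}]")


@dataclass
class LagSearchTrace:
    """Every evaluated lag vector with its AIC, and the accepted path."""

    evaluated: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    path: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    converged: bool = False

    def accepted_aics(self) -> np.ndarray:
        return np.array([a for _, a in self.path])


def compute_aic(fit: CasimFit) -> float:
    """AIC at fixed sample size: log MSE + 2m/n."""
    if fit.mse <= 0:
        raise ValueError("AIC undefined for non-positive MSE")
    m = _param_count(fit.lags, fit.growth is not None)
    return float(np.log(fit.mse) + 2.0 * m / fit.n_used)


class _Evaluator:
    """Memoised AIC evaluation at a fixed trimmed sample."""

    def __init__(self, dataset, K, monotone, fit_kwargs):
        self.dataset = dataset
        self.K = K
        self.monotone = monotone
        kwargs = dict(SEARCH_FIT_DEFAULTS)
        kwargs.update(fit_kwargs or {})
        self.fit_kwargs = kwargs
        self.cache: dict[tuple[int, ...], float] = {}
        self.trace = LagSearchTrace()

    def __call__(self, lags) -> float:
        key = tuple(int(v) for v in lags)
        if key not in self.cache:
            try:
                fit = backfit(
                    self.dataset,
                    np.asarray(key),
                    monotone=self.monotone,
                    trim=self.K,
                    **self.fit_kwargs,
                )
            except Exception as exc:  # propagate with the offending lag vector
                raise RuntimeError(f"model fit failed at lags {key}") from exc
            self.cache[key] = compute_aic(fit)
            self.trace.evaluated.append((key, self.cache[key]))
        return self.cache[key]


def common_lag_scan(
    dataset: TimeSeriesDataset,
    l: int = 10,
    K: int = 200,
    monotone=None,
    grid_start: int = 1,
    fit_kwargs: dict | None = None,
    evaluator: _Evaluator | None = None,
) -> int:
    """AIC-minimising common lag k over the grid {grid_start, +l, …, ≤K}.

    Ties break toward the smallest k.
    """
    if l < 1 or K < 1:
        raise ValueError("need l >= 1 and K >= 1")
    ev = evaluator or _Evaluator(dataset, K, monotone, fit_kwargs)
    grid = list(range(grid_start, K + 1, l))
    if not grid:
        raise ValueError("empty common-lag grid")
    p = len(dataset.covariate_names)
    best_k, best_aic = None, np.inf
    for k in grid:
        aic = ev([k] * p)
        logger.info("common-lag scan k=%d AIC=%.6f", k, aic)
        if best_k is None or aic < best_aic:  # strict: ties keep smaller k
            best_k, best_aic = k, aic
    return best_k


def coordinate_refine(
    dataset: TimeSeriesDataset,
    init,
    d: int = 5,
    K: int = 200,
    monotone=None,
    min_lag: int = 0,
    max_cycles: int = 50,
    fit_kwargs: dict | None = None,
    evaluator: _Evaluator | None = None,
) -> tuple[LagStructure, LagSearchTrace]:
    """Cyclic coordinate descent on the lag vector over ±d windows.

    Each coordinate is replaced by the AIC minimiser over
    [L_j − d, L_j + d] ∩ [min_lag, K] holding the others fixed; the
    search stops when a full cycle changes nothing.  Accepted AIC values
    are non-increasing by construction; repeated lag vectors are
    memoised.
    """
    ev = evaluator or _Evaluator(dataset, K, monotone, fit_kwargs)
    lags = np.asarray(init.lags if isinstance(init, LagStructure) else init, dtype=int)
    p = lags.size
    current_aic = ev(lags)
    ev.trace.path.append((tuple(lags), current_aic))
    for _ in range(max_cycles):
        changed = False
        for j in range(p):
            lo = max(min_lag, lags[j] - d)
            hi = min(K, lags[j] + d)
            best_k, best_aic = lags[j], current_aic
            for k in range(lo, hi + 1):
                cand = lags.copy()
                cand[j] = k
                aic = ev(cand)
                if aic < best_aic - 1e-12 or (
                    abs(aic - best_aic) <= 1e-12 and k < best_k
                ):
                    best_k, best_aic = k, aic
            if best_k != lags[j]:
                lags[j] = best_k
                current_aic = best_aic
                ev.trace.path.append((tuple(lags), current_aic))
                changed = True
        if not changed:
            ev.trace.converged = True
            break
    return LagStructure(lags=lags, K=K), ev.trace


def select_lags(
    dataset: TimeSeriesDataset,
    l: int = 10,
    K: int = 200,
    d: int = 5,
    monotone=None,
    grid_start: int = 1,
    min_lag: int = 0,
    fit_kwargs: dict | None = None,
) -> tuple[LagStructure, LagSearchTrace]:
    """Common-lag scan followed by coordinate refinement."""
    ev = _Evaluator(dataset, K, monotone, fit_kwargs)
    p = len(dataset.covariate_names)
    k0 = common_lag_scan(
        dataset, l=l, K=K, monotone=monotone, grid_start=grid_start, evaluator=ev
    )
    logger.info("common-lag scan selected k0=%d", k0)
    return coordinate_refine(
        dataset,
        np.full(p, k0),
        d=d,
        K=K,
        monotone=monotone,
        min_lag=min_lag,
        evaluator=ev,
    )
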