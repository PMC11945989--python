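"""Index transform and B-spline basis construction.

The single-index value v = θᵀX_j,t lives on the covariate scale.  Before
spline fitting it is mapped to the unit interval with the CDF of a
symmetric Beta{(d+1)/2, (d+1)/2} law rescaled and centred on [−a, a],
where d is the lag order of the block and a is an empirical scale (the
95th percentile of the per-row sup norms of the lagged block).  Cubic
B-splines are then built on quantile-placed interior knots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import betainc, gammaln

logger = logging.getLogger(__name__)

SPLINE_ORDER = 4  # cubic


@dataclass(frozen=True)
class IndexTransform:
    """Map index values from [−a, a] to [0, 1].

    Parameters
    ----------
    lag : int
        Lag order d of the block (number of lags beyond the current day).
    scale : float
        Positive half-width a of the support, in covariate units.
    """

    lag: int
    scale: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag order must be >= 0, got {self.lag}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be a positive finite real, got {self.scale}")


@dataclass(frozen=True)
class KnotSequence:
    """Interior knots in (0, 1) plus repeated boundary knots.

    The augmented sequence repeats 0 and 1 each ``order`` times, giving a
    B-spline basis of dimension ``len(interior) + order``.
    """

    interior: np.ndarray
    order: int = SPLINE_ORDER

    def __post_init__(self) -> None:
        interior = np.asarray(self.interior, dtype=float)
        object.__setattr__(self, "interior", interior)
        if interior.size and not (
            np.all(np.diff(interior) > 0)
            and interior[0] > 0.0
            and interior[-1] < 1.0
        ):
            raise ValueError("interior knots must be strictly increasing within (0, 1)")
        if self.order < 1:
            raise ValueError("spline order must be >= 1")

    @property
    def augmented(self) -> np.ndarray:
        k = self.order
        return np.concatenate([np.zeros(k), self.interior, np.ones(k)])

    @property
    def dimension(self) -> int:
        return self.interior.size + self.order


def quantile_nearest_rank(x: np.ndarray, q: float) -> float:
    """Type-1 (nearest-rank) empirical quantile, used throughout the package."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    idx = max(int(math.ceil(q * n)) - 1, 0)
    return float(x[min(idx, n - 1)])


def rescaled_beta_cdf(v, transform: IndexTransform):
    """CDF F_d of the symmetric Beta law on [−a, a], evaluated at v.

    Values outside [−a, a] are clamped to the support boundary so the
    result always lies in [0, 1].  Vectorised over v.
    """
    alpha = (transform.lag + 1) / 2.0
    z = np.clip(np.asarray(v, dtype=float) / transform.scale, -1.0, 1.0)
    out = betainc(alpha, alpha, (z + 1.0) / 2.0)
    return out if out.ndim else float(out)


def rescaled_beta_pdf(v, transform: IndexTransform):
    """Density of F_d on [−a, a]; zero outside the support.

    Needed for the analytic gradient of the index-weight objective.
    """
    d, a = transform.lag, transform.scale
    alpha = (d + 1) / 2.0
    z = np.asarray(v, dtype=float) / a
    inside = np.abs(z) <= 1.0
    # log normaliser of (1−t²)^{(d−1)/2} on [−1, 1]
    log_c = gammaln(d + 1) - 2.0 * gammaln(alpha) - d * math.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logdens = log_c + ((d - 1) / 2.0) * np.log(
            np.where(inside, np.maximum(1.0 - z**2, 0.0), 1.0)
        )
    dens = np.where(inside, np.exp(logdens) / a, 0.0)
    # d = 0 puts infinite density spikes at ±1; cap at the clamped boundary
    dens = np.where(np.isfinite(dens), dens, 0.0)
    return dens if dens.ndim else float(dens)


def select_scale(lagged_block: np.ndarray) -> float:
    """95th percentile (nearest-rank) of per-row sup norms of a lagged block."""
    block = np.asarray(lagged_block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.size == 0:
        raise ValueError("empty lagged block")
    if not np.all(np.isfinite(block)):
        raise ValueError("lagged block contains non-finite values")
    sup = np.max(np.abs(block), axis=1)
    a = quantile_nearest_rank(sup, 0.95)
    if a <= 0:
        raise ValueError("index scale a is zero: block has no signal at the 95th percentile")
    return a


def knot_count(n: int) -> int:
    """Interior-knot count rule N = max(floor(n^{1/5.5}), 5)."""
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    return max(int(math.floor(n ** (1.0 / 5.5))), 5)


def place_knots(u: np.ndarray, n_knots: int, order: int = SPLINE_ORDER) -> KnotSequence:
    """Interior knots at the j/(N+1) empirical quantiles of u, j = 1..N.

    Duplicate knots (heavy ties in u) are collapsed with a warning and the
    effective N reduced; quantiles falling on 0 or 1 are dropped likewise.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("empty index sample")
    if np.min(u) < 0.0 or np.max(u) > 1.0:
        raise ValueError("index values must lie in [0, 1]")
    if n_knots < 1:
        raise ValueError("need at least one interior knot")
    probs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.array([quantile_nearest_rank(u, q) for q in probs])
    unique = np.unique(knots)
    unique = unique[(unique > 0.0) & (unique < 1.0)]
    if unique.size < n_knots:
        logger.warning(
            "collapsed %d duplicate/boundary interior knots (ties in the index sample)",
            n_knots - unique.size,
        )
    return KnotSequence(interior=unique, order=order)


def bspline_design(u: np.ndarray, knots: KnotSequence) -> np.ndarray:
    """Dense n × (N + k) B-spline design matrix at points u in [0, 1]."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.size and (np.min(u) < 0.0 or np.max(u) > 1.0):
        raise ValueError("evaluation points must lie in [0, 1]")
    return BSpline.design_matrix(u, knots.augmented, knots.order - 1).toarray()


def spline_value(u, knots: KnotSequence, coefficients: np.ndarray):
    """Evaluate the spline with the given coefficients at u in [0, 1]."""
    sp = BSpline(knots.augmented, np.asarray(coefficients, dtype=float), knots.order - 1)
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    out = sp(u)
    return out if out.ndim else float(out)


def spline_derivative(u, knots: KnotSequence, coefficients: np.ndarray):
    """Derivative of the spline at u (boundary-clamped)."""
    sp = BSpline(
        knots.augmented, np.asarray(coefficients, dtype=float), knots.order - 1
    ).derivative()
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    out = sp(u)
    return out if out.ndim else float(out)
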