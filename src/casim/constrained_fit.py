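"""Constrained estimation for one covariate's single-index block.

A block models the cumulative effect g_j(θ_jᵀ X_j,t) of one covariate's
lag window.  The lag weights θ_j live on the *ordered simplex*
{θ : θ_0 ≥ θ_1 ≥ … ≥ θ_L ≥ 0, Σθ = 1}; the effect curve g_j is a cubic
B-spline in the transformed index u = F_d(θᵀX), optionally constrained to
be non-decreasing via non-decreasing spline coefficients (restricted
least squares).  Estimation alternates restricted spline regression with
gradient-projection steps on θ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import isotonic_regression, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .basis import (
    IndexTransform,
    KnotSequence,
    bspline_design,
    knot_count,
    place_knots,
    rescaled_beta_cdf,
    rescaled_beta_pdf,
    select_scale,
    spline_derivative,
    spline_value,
)

logger = logging.getLogger(__name__)

RIDGE = 1e-8  # fallback regularisation for collapsed design columns


@dataclass(frozen=True)
class IndexWeights:
    """Lag-weight vector on the ordered simplex for one covariate block."""

    theta: np.ndarray
    lag: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.size != self.lag + 1:
            raise ValueError("theta must have length lag + 1")
        if abs(theta.sum() - 1.0) > 1e-8:
            raise ValueError("theta must sum to 1")
        if np.any(np.diff(theta) > 1e-10) or theta[-1] < -1e-12:
            raise ValueError("theta must be non-increasing and non-negative")


@dataclass(frozen=True)
class EffectFunction:
    """Fitted spline effect curve with its index transform.

    ``__call__`` evaluates the centred curve at index values v on the
    covariate scale: g(v) = γ(F_d(v)) − centering_offset.
    """

    transform: IndexTransform
    knots: KnotSequence
    coefficients: np.ndarray
    monotone: bool
    centering_offset: float = 0.0

    def index_to_unit(self, v):
        return rescaled_beta_cdf(v, self.transform)

    def __call__(self, v):
        return spline_value(self.index_to_unit(v), self.knots, self.coefficients) - (
            self.centering_offset
        )

    def on_unit(self, u):
        """Evaluate the centred curve directly on the unit interval."""
        return spline_value(u, self.knots, self.coefficients) - self.centering_offset

    def centred(self, offset_shift: float) -> "EffectFunction":
        return replace(self, centering_offset=self.centering_offset + offset_shift)


def project_to_ordered_simplex(raw: np.ndarray) -> IndexWeights:
    """Euclidean projection onto the ordered unit simplex.

    Solves min ‖θ − raw‖² s.t. θ_0 ≥ … ≥ θ_L ≥ 0, Σθ = 1 exactly: for a
    sum-constraint multiplier λ the solution is the clipped decreasing
    isotonic regression of raw − λ, and Σθ(λ) is non-increasing in λ, so
    bisection on λ closes the problem.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty weight vector")
    if not np.all(np.isfinite(raw)):
        raise ValueError("weight vector contains non-finite values")
    if raw.size == 1:
        return IndexWeights(theta=np.array([1.0]), lag=0)

    def proj_cone(lam: float) -> np.ndarray:
        fit = isotonic_regression(raw - lam, increasing=False).x
        return np.maximum(fit, 0.0)

    lo, hi = np.min(raw) - 1.0, np.max(raw)
    while proj_cone(lo).sum() < 1.0:
        lo -= 2.0 * (hi - lo)
    while proj_cone(hi).sum() > 1.0:
        hi += 2.0 * (hi - lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if proj_cone(mid).sum() > 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    theta = proj_cone(0.5 * (lo + hi))
    s = theta.sum()
    if s <= 0:  # numerically degenerate; fall back to uniform
        theta = np.full(raw.size, 1.0 / raw.size)
    else:
        theta = theta / s
    theta = np.maximum(isotonic_regression(theta, increasing=False).x, 0.0)
    theta /= theta.sum()
    return IndexWeights(theta=theta, lag=raw.size - 1)


def _solve_ls(design: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least squares with a tiny-ridge fallback for rank-deficient designs."""
    coef, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient spline design; applying ridge %.0e", RIDGE)
        gram = design.T @ design + RIDGE * np.eye(design.shape[1])
        coef = np.linalg.solve(gram, design.T @ z)
    return coef


def _monotone_coef_ls(design: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Restricted least squares with non-decreasing coefficients.

    Reparametrises β = Cγ (C lower-triangular ones) so β is non-decreasing
    iff γ_2.. ≥ 0.  Because the basis is a partition of unity the first
    column of the transformed design is constant, so the level γ_1 is
    profiled out and the rest solved by NNLS — an exact restricted fit.
    """
    n, m = design.shape
    cum = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]  # column j: Σ_{i>=j} B_i
    a2 = cum[:, 1:]
    zc = z - z.mean()
    a2c = a2 - a2.mean(axis=0)
    gamma2, _ = nnls(a2c, zc, maxiter=10 * m)
    gamma1 = float(np.mean(z - a2 @ gamma2))
    beta = gamma1 + np.concatenate([[0.0], np.cumsum(gamma2)])
    return beta


class MonotoneSplineRegressor(BaseEstimator, RegressorMixin):
    """Cubic B-spline regression on [0, 1], optionally shape-restricted.

    With ``monotone=True`` the coefficients are constrained to be
    non-decreasing, which is sufficient for a non-decreasing spline.

    Parameters
    ----------
    monotone : bool, default True
        Require a non-decreasing fit.
    knots : KnotSequence, optional
        Fixed knot sequence; by default placed at empirical quantiles of
        the training inputs with the N = max(n^{1/5.5}, 5) count rule.
    """

    def __init__(self, monotone: bool = True, knots: KnotSequence | None = None):
        self.monotone = monotone
        self.knots = knots

    def fit(self, X, y):
        u = np.asarray(X, dtype=float).reshape(-1)
        z = np.asarray(y, dtype=float).reshape(-1)
        if u.size != z.size:
            raise ValueError("X and y lengths differ")
        knots = self.knots if self.knots is not None else place_knots(u, knot_count(u.size))
        design = bspline_design(u, knots)
        if z.size < design.shape[1]:
            raise ValueError(
                f"need at least {design.shape[1]} observations for a "
                f"{design.shape[1]}-dimensional basis, got {z.size}"
            )
        if self.monotone:
            coef = _monotone_coef_ls(design, z)
        else:
            coef = _solve_ls(design, z)
        self.knots_ = knots
        self.coef_ = coef
        resid = z - design @ coef
        self.rss_ = float(resid @ resid)
        return self

    def predict(self, X):
        u = np.asarray(X, dtype=float).reshape(-1)
        return spline_value(u, self.knots_, self.coef_)


def _fit_spline_block(
    z: np.ndarray,
    u: np.ndarray,
    monotone: bool,
    transform: IndexTransform,
    knots: KnotSequence | None = None,
) -> tuple[EffectFunction, float]:
    reg = MonotoneSplineRegressor(monotone=monotone, knots=knots).fit(u, z)
    effect = EffectFunction(
        transform=transform,
        knots=reg.knots_,
        coefficients=reg.coef_,
        monotone=monotone,
    )
    return effect, reg.rss_


def fit_monotone_spline(Z, u, knots: KnotSequence) -> EffectFunction:
    """Non-decreasing spline fit of Z on u ∈ [0, 1] at fixed knots."""
    effect, _ = _fit_spline_block(
        np.asarray(Z, float), np.asarray(u, float), True, IndexTransform(0, 1.0), knots
    )
    return effect


def fit_unconstrained_spline(Z, u, knots: KnotSequence) -> EffectFunction:
    """Ordinary least-squares spline fit of Z on u ∈ [0, 1] at fixed knots."""
    effect, _ = _fit_spline_block(
        np.asarray(Z, float), np.asarray(u, float), False, IndexTransform(0, 1.0), knots
    )
    return effect


class SingleIndexRegressor(BaseEstimator, RegressorMixin):
    """Constrained single-index spline regression for one lagged block.

    Fits Z_t ≈ g(θᵀX_t) where the rows of X are a covariate's lag window
    (current value first), θ is on the ordered simplex and g is a cubic
    spline in the Beta-transformed index, optionally non-decreasing.
    Estimation alternates restricted spline fits with projected-gradient
    steps on θ (Armijo backtracking); a candidate θ is accepted only if
    the fully refreshed objective decreases, so the RSS sequence is
    monotone non-increasing.

    Attributes
    ----------
    weights_ : IndexWeights
    effect_ : EffectFunction
    rss_ : float
    n_iter_ : int
    converged_ : bool
    warned_ : bool
        True when the search stopped because no descent step was found.
    """

    def __init__(
        self,
        monotone_g: bool = True,
        init: IndexWeights | None = None,
        tol: float = 1e-6,
        max_iter: int = 50,
        max_backtracks: int = 30,
    ):
        self.monotone_g = monotone_g
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.max_backtracks = max_backtracks

    def fit(self, X, y):
        block = np.asarray(X, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        z = np.asarray(y, dtype=float).reshape(-1)
        n, width = block.shape
        if z.size != n:
            raise ValueError("response and lagged block are not aligned")
        lag = width - 1
        scale = select_scale(block)
        transform = IndexTransform(lag=lag, scale=scale)
        n_knots = knot_count(n)

        def assemble(theta: np.ndarray):
            v = block @ theta
            u = rescaled_beta_cdf(v, transform)
            effect, rss = _fit_spline_block(
                z, u, self.monotone_g, transform, place_knots(u, n_knots)
            )
            if not np.isfinite(rss):
                raise FloatingPointError("non-finite single-index objective")
            return effect, rss

        if self.init is not None:
            if self.init.lag != lag:
                raise ValueError("init weights have the wrong lag order")
            theta = self.init.theta.copy()
        else:
            theta = np.full(width, 1.0 / width)

        effect, rss = assemble(theta)
        self.converged_ = False
        self.warned_ = False
        n_iter = 0
        if lag == 0:
            theta = np.array([1.0])
            effect, rss = assemble(theta)
            self.converged_ = True
        else:
            for n_iter in range(1, self.max_iter + 1):
                v = block @ theta
                u = rescaled_beta_cdf(v, transform)
                resid = z - spline_value(u, effect.knots, effect.coefficients)
                chain = spline_derivative(u, effect.knots, effect.coefficients)
                dens = rescaled_beta_pdf(v, transform)
                grad = -2.0 * block.T @ (resid * chain * dens)
                gnorm = np.linalg.norm(grad)
                if gnorm == 0.0:
                    self.converged_ = True
                    break
                step = 1.0 / max(gnorm, 1.0)
                accepted = False
                for _ in range(self.max_backtracks):
                    cand = project_to_ordered_simplex(theta - step * grad).theta
                    if np.allclose(cand, theta, atol=1e-14):
                        break
                    cand_effect, cand_rss = assemble(cand)
                    if cand_rss < rss - 1e-14:
                        theta, effect, prev_rss, rss = cand, cand_effect, rss, cand_rss
                        accepted = True
                        break
                    step *= 0.5
                if not accepted:
                    # no descent direction left: at a constrained stationary point
                    self.converged_ = True
                    break
                if prev_rss - rss <= self.tol * max(prev_rss, 1e-300):
                    self.converged_ = True
                    break
            else:
                self.warned_ = True
                warnings.warn(
                    "single-index fit reached max_iter without meeting tolerance",
                    stacklevel=2,
                )

        self.weights_ = IndexWeights(theta=theta, lag=lag)
        self.effect_ = effect
        self.rss_ = rss
        self.n_iter_ = n_iter
        return self

    def predict(self, X):
        block = np.asarray(X, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        return self.effect_(block @ self.weights_.theta)


def fit_single_index(
    Z,
    lagged_block,
    monotone_g: bool = True,
    init: IndexWeights | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[IndexWeights, EffectFunction]:
    """Functional wrapper over :class:`SingleIndexRegressor`."""
    reg = SingleIndexRegressor(
        monotone_g=monotone_g, init=init, tol=tol, max_iter=max_iter
    ).fit(lagged_block, Z)
    return reg.weights_, reg.effect_
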