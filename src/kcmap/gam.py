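"""Smooth marker transformation and multi-marker combination.

Some diagnostic markers are not monotonically related to disease (the
thin-point vertical location is the canonical example: both strongly
inferior and strongly superior thin points can be abnormal).  The ROC
curve of such a marker understates its information.  The remedy used
here is the logistic generalized additive model: fit

    logit P(diseased | marker = x) = f(x),    f = B-spline expansion,

with a second-order difference penalty on the spline coefficients
(a P-spline), by penalized iteratively reweighted least squares, the
smoothing parameter chosen by generalized cross-validation over a fixed
log-spaced grid.  The fitted probability is then used as a transformed
marker; for a monotone marker the transform is monotone and the ROC
curve is unchanged, while a U-shaped risk is folded into a monotone
probability scale.

Multi-marker combination uses the same IRLS machinery with an identity
basis and no penalty: a plain maximum-likelihood logistic model whose
linear predictor serves as the combined marker.

In the heavy-smoothing limit the second-order penalty shrinks f to a
linear function, so the P-spline fit approaches the plain logistic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 20)


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class SeparationWarning(UserWarning):
    """(Quasi-)complete separation detected; fit was ridge-stabilized."""


# --------------------------------------------------------------------------
# basis and penalty


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """B-spline design matrix on a full (clamped) knot vector."""
    n_basis = len(knots) - degree - 1
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()[:, :n_basis]


def make_knots(lo: float, hi: float, n_basis: int = 12, degree: int = 3) -> np.ndarray:
    """Clamped uniform knot vector spanning [lo, hi] with ``n_basis``
    basis functions."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for the degree")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def second_diff_penalty(n_basis: int) -> np.ndarray:
    """D2'D2 penalty matrix on spline coefficients (nullspace: linear
    coefficient sequences)."""
    d2 = np.diff(np.eye(n_basis), n=2, axis=0)
    return d2.T @ d2


# --------------------------------------------------------------------------
# penalized IRLS core


def _pirls(X, y, penalty, lam, ridge=1e-9, max_iter=100, tol=1e-9):
    """Penalized IRLS for Bernoulli-logit.  Returns (beta, edf, deviance,
    n_iter).  Raises ConvergenceError when the budget is exhausted."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = np.zeros(n)
    pen = lam * penalty + ridge * np.eye(p)
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + pen
        beta_new = np.linalg.solve(A, XtW @ z)
        eta = X @ beta_new
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        if np.abs(dev - dev_old) < tol * (np.abs(dev) + 0.1):
            beta = beta_new
            break
        beta, dev_old = beta_new, dev
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(deviance {dev:.3g}, max|beta| {np.abs(beta).max():.3g})"
        )
    mu = np.clip(1.0 / (1.0 + np.exp(-X @ beta)), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    XtW = X.T * w
    A = XtW @ X + pen
    edf = float(np.trace(np.linalg.solve(A, XtW @ X)))
    dev = float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return beta, edf, dev, it


def _fit_logistic(X, y, penalty=None, lam=0.0, max_iter=100):
    """IRLS fit with separation fallback: on divergence or non-convergence
    the fit is repeated with a small ridge and a SeparationWarning."""
    p = X.shape[1]
    penalty = np.zeros((p, p)) if penalty is None else penalty
    try:
        beta, edf, dev, _ = _pirls(X, y, penalty, lam)
        # a deviance of ~0 means every case is fitted exactly: separation
        if np.abs(beta).max() < 1e3 and dev > 1e-6 * X.shape[0]:
            return beta, edf, dev, False
        raise ConvergenceError("diverging coefficients")
    except (ConvergenceError, np.linalg.LinAlgError):
        warnings.warn(
            "possible separation; refitting with ridge stabilization",
            SeparationWarning, stacklevel=3,
        )
        beta, edf, dev, _ = _pirls(X, y, penalty, lam, ridge=1e-4 * X.shape[0])
        return beta, edf, dev, True


# --------------------------------------------------------------------------
# GAM marker transform


@dataclass(frozen=True)
class MarkerTransform:
    """Fitted P-spline logistic transform: marker value -> P(diseased).

    Inputs outside the training range are clamped to its ends, so the
    transform is defined (and constant) beyond the observed marker
    range.
    """

    knots: np.ndarray
    degree: int
    coef: np.ndarray
    lam: float
    edf: float
    gcv_table: pd.DataFrame | None = None
    ridged: bool = False

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def linear_predictor(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return bspline_design(x, self.knots, self.degree) @ self.coef

    def __call__(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(x)))


def gam_transform(
    marker,
    labels,
    n_basis: int = 12,
    degree: int = 3,
    lambda_grid: np.ndarray | None = None,
    fixed_lambda: float | None = None,
) -> MarkerTransform:
    """Fit the penalized B-spline logistic transform of one marker.

    The smoothing parameter minimizes the GCV score
    ``n * deviance / (n - edf)^2`` over a fixed log-spaced grid unless
    ``fixed_lambda`` is given.  Requires both classes and n >= 20.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(labels).astype(float)
    if x.size < 20:
        raise ValueError("GAM transform requires n >= 20")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("marker is constant")
    knots = make_knots(lo, hi, n_basis, degree)
    X = bspline_design(x, knots, degree)
    P = second_diff_penalty(X.shape[1])

    if fixed_lambda is not None:
        beta, edf, dev, ridged = _fit_logistic(X, y, P, float(fixed_lambda))
        return MarkerTransform(knots, degree, beta, float(fixed_lambda), edf, None, ridged)

    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    rows, fits = [], {}
    n = x.size
    for lam in grid:
        beta, edf, dev, ridged = _fit_logistic(X, y, P, float(lam))
        gcv = n * dev / (n - edf) ** 2
        rows.append({"lambda": float(lam), "edf": edf, "deviance": dev, "gcv": gcv})
        fits[float(lam)] = (beta, edf, ridged)
    table = pd.DataFrame(rows)
    best = float(table.loc[table["gcv"].idxmin(), "lambda"])
    beta, edf, ridged = fits[best]
    return MarkerTransform(knots, degree, beta, best, edf, table, ridged)


@dataclass(frozen=True)
class MonotonicityResult:
    monotone: bool
    degenerate: bool = False
    increasing: bool | None = None


def monotonicity_check(
    marker, labels, n_grid: int = 200, rel_tol: float = 0.01
) -> MonotonicityResult:
    """Is the smooth marker-risk relationship monotone?

    Fits the default GAM transform and inspects the sign of the fitted
    slope across the observed marker range, with a tolerance band of
    ``rel_tol`` times the maximum absolute slope to ignore numerically
    flat wiggles.  A constant marker is reported as degenerate (treated
    as monotone: no transform is warranted).
    """
    x = np.asarray(marker, dtype=float)
    if x.size < 20:
        raise ValueError("monotonicity check requires n >= 20")
    if x.min() == x.max():
        return MonotonicityResult(monotone=True, degenerate=True)
    tf = gam_transform(x, labels)
    gx = np.linspace(x.min(), x.max(), n_grid)
    slope = np.diff(tf.linear_predictor(gx))
    scale = np.abs(slope).max()
    if scale == 0:
        return MonotonicityResult(monotone=True, degenerate=True)
    band = rel_tol * scale
    up, down = (slope > band).any(), (slope < -band).any()
    if up and down:
        return MonotonicityResult(monotone=False, increasing=None)
    return MonotonicityResult(monotone=True, increasing=bool(up))


# --------------------------------------------------------------------------
# GLM combination


@dataclass(frozen=True)
class CombinedModel:
    """Logistic combination of several features; the linear predictor is
    the combined diagnostic marker."""

    feature_names: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    deviance: float
    ridged: bool = False

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(features)))


def glm_combine(features: pd.DataFrame, labels, columns: list[str] | None = None) -> CombinedModel:
    """Maximum-likelihood logistic combination of the given feature
    columns.

    Errors on constant or collinear columns (naming them); warns and
    ridge-stabilizes under separation.  Requires n > p + 1.
    """
    columns = list(columns or features.columns)
    X0 = features.loc[:, columns].to_numpy(dtype=float)
    y = np.asarray(labels).astype(float)
    n, p = X0.shape
    if n <= p + 1:
        raise ValueError("need more observations than features + 1")
    const = [c for c, col in zip(columns, X0.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant feature columns: {const}")
    # standardize for numerical conditioning; coefficients mapped back below
    mu, sd = X0.mean(axis=0), X0.std(axis=0)
    Xs = (X0 - mu) / sd
    X = np.column_stack([np.ones(n), Xs])
    if np.linalg.matrix_rank(X) < p + 1:
        corr = np.corrcoef(Xs.T)
        bad = sorted(
            {columns[i] for i in range(p) for j in range(i + 1, p)
             if abs(corr[i, j]) > 1 - 1e-10} or set(columns)
        )
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, dev, ridged = _fit_logistic(X, y)
    coef = beta[1:] / sd
    intercept = float(beta[0] - (mu / sd) @ beta[1:])
    return CombinedModel(tuple(columns), intercept, coef, float(dev), ridged)
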