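"""Correlation, regression, and BIC-based model selection.

Model selection compares polynomials of degree 2..10 with a continuous
two-piece linear model.  For least-squares fits with Gaussian errors the
Bayesian information criterion reduces to

    BIC = K ln(n) + n ln(sigma^2),

with K the number of estimated parameters, n the sample size and sigma^2
the mean squared residual; the general form K ln(n) - 2 ln(L_hat) differs
only by the model-independent constant n (ln 2 pi + 1) and ranks models
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import CorrelationResult, InputError

SIGMA2_FLOOR = 1e-12


def pearson_r(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("undefined correlation: zero variance")
    r = stats.pearsonr(x, y).statistic
    return CorrelationResult(x_label, y_label, float(r), int(x.size))


def ols_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InputError("regression requires n >= 3")
    if np.std(x) == 0:
        raise InputError("constant x")
    if np.std(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class ModelFit:
    family: str                  # "polynomial" or "piecewise_linear_2"
    degree: int | None
    coefficients: np.ndarray     # polynomial: ascending powers
    breakpoint: float | None
    K: int
    n: int
    sigma2: float
    bic: float
    perfect_fit: bool = False
    fitted: np.ndarray = field(default=None, repr=False)

    @property
    def label(self) -> str:
        if self.family == "polynomial":
            return f"poly{self.degree}"
        return "piecewise_linear_2"


def bic_from_sigma2(K: int, n: int, sigma2: float) -> float:
    return K * np.log(n) + n * np.log(max(sigma2, SIGMA2_FLOOR))


def bic_gaussian(K: int, n: int, sigma2: float) -> float:
    """General form K ln n - 2 ln L_hat with the Gaussian likelihood
    maximized at sigma_hat^2 (used as an equivalence check)."""
    s2 = max(sigma2, SIGMA2_FLOOR)
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return K * np.log(n) - 2.0 * loglik


def fit_polynomial_bic(x, y, degree: int) -> ModelFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    K = degree + 1
    n = x.size
    if n <= K:
        raise InputError(f"need n > K = {K} points for degree {degree}")
    # Vandermonde least squares on standardized x for conditioning
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    V = np.vander(xs, K, increasing=True)
    coef_s, *_ = np.linalg.lstsq(V, y, rcond=None)
    fitted = V @ coef_s
    sigma2 = float(np.mean((y - fitted) ** 2))
    # map coefficients back to the raw-x basis
    poly = np.polynomial.Polynomial(coef_s)(
        np.polynomial.Polynomial([-mu / sd, 1.0 / sd]))
    return ModelFit("polynomial", degree, poly.coef, None, K, n, sigma2,
                    bic_from_sigma2(K, n, sigma2),
                    perfect_fit=sigma2 < SIGMA2_FLOOR, fitted=fitted)


def fit_piecewise_linear_bic(x, y, n_grid: int = 50) -> ModelFit:
    """Continuous two-piece linear fit.

    The breakpoint is grid-searched over interior x-quantiles (outer 5%
    excluded) with per-breakpoint least squares on the hinge basis
    [1, x, max(0, x - c)].  K = 4: two slopes, one intercept, and the
    searched breakpoint.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 6:
        raise InputError("piecewise fit requires n >= 6")
    if np.unique(x).size < 4:
        raise InputError("piecewise fit requires >= 4 distinct x values")
    qs = np.linspace(0.05, 0.95, n_grid)
    grid = np.unique(np.quantile(x, qs))
    best = None
    for c in grid:
        X = np.column_stack([np.ones(n), x, np.maximum(0.0, x - c)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, c, coef, X @ coef)
    sse, c, coef, fitted = best
    sigma2 = sse / n
    K = 4
    return ModelFit("piecewise_linear_2", None,
                    np.array([coef[0], coef[1], coef[1] + coef[2]]),
                    float(c), K, n, sigma2, bic_from_sigma2(K, n, sigma2),
                    perfect_fit=sigma2 < SIGMA2_FLOOR, fitted=fitted)


def select_model(x, y, degree_min: int = 2, degree_max: int = 10) -> list[ModelFit]:
    """Fit all candidate models and rank by BIC (ties -> lower K).

    Returns the fits sorted best-first; the winner is ``result[0]``.
    """
    fits = [fit_polynomial_bic(x, y, d)
            for d in range(degree_min, degree_max + 1)]
    fits.append(fit_piecewise_linear_bic(x, y))
    fits.sort(key=lambda f: (f.bic, f.K))
    return fits
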