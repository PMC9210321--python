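"""Weighted regression and test machinery.

Weights throughout are inverse squared standard errors of the fitness
estimates (relative precisions, not frequency weights): every statistic
here is invariant under rescaling all weights by a positive constant.
Weighted least squares is delegated to statsmodels; the likelihood-ratio
test, the single-random-intercept ML fit, the weighted Pearson
correlation, the weighted Welch's t-test and weighted quantiles are
implemented against the conventions documented on each function.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import linalg, optimize, stats

from .types import AMINO_ACIDS, CompositionRecord, RegressionFit

logger = logging.getLogger(__name__)


def detect_collinear(X: np.ndarray, names: Optional[Sequence[str]] = None) -> list[str]:
    """Names (or indices) of columns that make X rank-deficient, via pivoted QR."""
    X = np.asarray(X, dtype=float)
    _, R, piv = linalg.qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    bad = np.concatenate([bad, piv[len(diag):]]).astype(int)
    if names is None:
        return [str(i) for i in sorted(bad)]
    return [names[i] for i in sorted(bad)]


def wls_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    names: Optional[list[str]] = None,
) -> RegressionFit:
    """Weighted least squares with adjusted R-squared.

    ``X`` must include the intercept column. The coefficient vector
    minimizes sum w_i (y_i - X_i beta)^2; R-squared is computed against
    the weighted mean; the Gaussian log-likelihood treats weights as
    inverse relative variances; the coefficient covariance is
    sigma2_hat * (X' W X)^-1. Rank-deficient designs raise an error that
    names the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, ncol = X.shape
    p = ncol - 1  # predictor degrees of freedom (intercept excluded)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < ncol:
        bad = detect_collinear(X * np.sqrt(w)[:, None], names)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    res = sm.WLS(y, X, weights=w).fit()
    r2 = float(res.rsquared)
    return RegressionFit(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        r2=r2,
        r2_adj=adjusted_r2(r2, n, p),
        n=n,
        p=p,
        names=list(names) if names else [f"x{i}" for i in range(ncol)],
        y=y,
        w=w,
        sigma2=float(res.ssr / n),
        group_var=0.0,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R2_adj = 1 - (1 - R2) * (n - 1) / (n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


class LRTResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def lrt(fit_null: RegressionFit, fit_full: RegressionFit) -> LRTResult:
    """Likelihood-ratio test of nested weighted models on identical (y, w)."""
    if fit_null.n != fit_full.n:
        raise ValueError("models were fitted to different numbers of observations")
    if fit_null.y is not None and fit_full.y is not None:
        if not (
            np.allclose(fit_null.y, fit_full.y) and np.allclose(fit_null.w, fit_full.w)
        ):
            raise ValueError("models must share the same response and weights")
    df = fit_full.p - fit_null.p
    if df < 0:
        raise ValueError("full model must have at least as many predictors as the null")
    statistic = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    if df == 0:
        # identical model structure: no test, p = 1 by convention
        return LRTResult(statistic, 0, 1.0)
    return LRTResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def random_intercept_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    groups: Sequence,
    names: Optional[list[str]] = None,
) -> RegressionFit:
    """ML fit of y = X beta + u_group + eps with one variance component.

    eps_i ~ N(0, sigma2 / w_i) and u_g ~ N(0, sigma2_u). The variance
    ratio theta = sigma2_u / sigma2 is profiled out on a log grid plus
    bounded refinement; theta = 0 reduces exactly to :func:`wls_fit`
    (same coefficients and log-likelihood). This is a plain ML (not REML)
    fit used as a cross-check on the cluster-collapsed fixed-effect
    regressions, with no claim of numeric parity with any particular
    mixed-model package.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        logger.warning("single group: falling back to wls_fit")
        return wls_fit(X, y, w, names=names)
    idx = [np.flatnonzero(groups == g) for g in labels]
    n, ncol = X.shape
    p = ncol - 1

    def profile(theta: float):
        # Woodbury: (diag(1/w) + theta 11')^-1 = diag(w) - theta ww'/(1 + theta * sum w)
        XtVX = np.zeros((ncol, ncol))
        XtVy = np.zeros(ncol)
        quad = 0.0
        logdet = 0.0
        # first pass for beta
        for ii in idx:
            Xg, yg, wg = X[ii], y[ii], w[ii]
            sw = wg.sum()
            c = theta / (1.0 + theta * sw)
            WX = wg[:, None] * Xg
            Wy = wg * yg
            XtVX += Xg.T @ WX - c * np.outer(WX.sum(0), WX.sum(0))
            XtVy += Xg.T @ Wy - c * WX.sum(0) * Wy.sum()
            logdet += -np.sum(np.log(wg)) + np.log1p(theta * sw)
        beta = np.linalg.solve(XtVX, XtVy)
        for ii in idx:
            Xg, yg, wg = X[ii], y[ii], w[ii]
            sw = wg.sum()
            c = theta / (1.0 + theta * sw)
            r = yg - Xg @ beta
            wr = wg * r
            quad += r @ wr - c * wr.sum() ** 2
        sigma2 = quad / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, XtVX

    # evaluate theta = 0 and a log grid, then refine around the best
    grid = np.concatenate([[0.0], np.exp(np.linspace(-12, 8, 41))])
    lls = [profile(t)[0] for t in grid]
    best = int(np.argmax(lls))
    theta = grid[best]
    if best > 0:
        lo = grid[best - 1] if best >= 1 else 0.0
        hi = grid[best + 1] if best + 1 < len(grid) else grid[best] * 10
        res = optimize.minimize_scalar(
            lambda t: -profile(t)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if -res.fun > lls[best]:
            theta = float(res.x)
    ll, beta, sigma2, XtVX = profile(theta)
    cov = sigma2 * np.linalg.inv(XtVX)
    resid = y - X @ beta
    ybar = np.average(y, weights=w)
    r2 = 1.0 - np.sum(w * resid**2) / np.sum(w * (y - ybar) ** 2)
    return RegressionFit(
        coefficients=beta,
        covariance=cov,
        loglik=float(ll),
        r2=float(r2),
        r2_adj=adjusted_r2(float(r2), n, p),
        n=n,
        p=p,
        names=list(names) if names else [f"x{i}" for i in range(ncol)],
        y=y,
        w=w,
        sigma2=float(sigma2),
        group_var=float(theta * sigma2),
    )


class PearsonResult(NamedTuple):
    r: float
    p_value: float


def weighted_pearson(x, y, w) -> PearsonResult:
    """Weighted Pearson correlation with a t-based two-sided p-value.

    The effective sample size for the test is the number of observations
    with nonzero weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    syy = np.sum(w * (y - ybar) ** 2)
    if sxx == 0 or syy == 0:
        raise ValueError("zero weighted variance in x or y")
    r = float(np.sum(w * (x - xbar) * (y - ybar)) / np.sqrt(sxx * syy))
    m = int(np.count_nonzero(w))
    if abs(r) >= 1.0:
        return PearsonResult(r, 0.0)
    tstat = r * np.sqrt((m - 2) / (1.0 - r**2))
    return PearsonResult(r, float(2 * stats.t.sf(abs(tstat), m - 2)))


class WelchResult(NamedTuple):
    t: float
    df: float
    p_value: float
    degenerate: bool = False


def weighted_welch_ttest(x1, w1, x2, w2) -> WelchResult:
    """Weighted Welch's t-test on two independent groups.

    Weights are first normalized within each group to sum to that group's
    number of (positively weighted) members; Welch's statistic is then
    computed from the weighted means and weighted variances with the
    Welch-Satterthwaite degrees of freedom. Equal weights reduce exactly
    to the classic Welch's t-test.
    """

    def moments(x, w):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        keep = w > 0
        x, w = x[keep], w[keep]
        n = len(x)
        if n < 2:
            raise ValueError("each group needs >= 2 members with positive weight")
        w = w * n / w.sum()
        m = np.average(x, weights=w)
        var = np.sum(w * (x - m) ** 2) / (n - 1)
        return n, m, var

    n1, m1, v1 = moments(x1, w1)
    n2, m2, v2 = moments(x2, w2)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        logger.info("degenerate Welch test: both groups have zero weighted variance")
        return WelchResult(0.0, float(n1 + n2 - 2), 1.0, degenerate=True)
    tstat = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return WelchResult(float(tstat), float(df), float(2 * stats.t.sf(abs(tstat), df)))


def weighted_quantile(x, w, q) -> float:
    """Type-7-style weighted quantile.

    Observations are placed at their midpoint cumulative weights and the
    quantile is linear interpolation between them; with equal weights this
    is exactly numpy's default (type 7) quantile.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = w > 0
    x, w = x[keep], w[keep]
    order = np.argsort(x)
    x, w = x[order], w[order]
    h = np.cumsum(w) - w / 2.0
    target = h[0] + q * (h[-1] - h[0])
    return float(np.interp(target, h, x))


def quantile_effect_size(
    fit: RegressionFit, predictor_values, w, q_lo: float = 0.1, q_hi: float = 0.9
) -> tuple[float, float]:
    """Model predictions at the weighted q_lo and q_hi predictor quantiles.

    Quantifies the effect size of a single-predictor model as the change
    in predicted fitness across the bulk of the predictor distribution.
    """
    if not (0 < q_lo < q_hi < 1):
        raise ValueError("need 0 < q_lo < q_hi < 1")
    if len(fit.coefficients) != 2:
        raise ValueError("quantile_effect_size expects a single-predictor fit")
    x_lo = weighted_quantile(predictor_values, w, q_lo)
    x_hi = weighted_quantile(predictor_values, w, q_hi)
    pred = fit.predict(np.array([[1.0, x_lo], [1.0, x_hi]]))
    return float(pred[0]), float(pred[1])


def aa_frequency_design(
    comps: Sequence[CompositionRecord], drop: str = "A"
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the amino-acid-frequency fitness model.

    The 20 frequencies sum to 1, so intercept + 20 columns is
    rank-deficient; one residue column (alanine by default) is dropped,
    leaving the model's 19 frequency degrees of freedom. Marginal effects
    downstream are invariant to which column is dropped.
    """
    if drop not in AMINO_ACIDS:
        raise ValueError(f"unknown residue {drop!r}")
    kept = [a for a in AMINO_ACIDS if a != drop]
    X = np.column_stack(
        [np.ones(len(comps))]
        + [[c.freq_vector()[AMINO_ACIDS.index(a)] for c in comps] for a in kept]
    )
    names = ["intercept"] + [f"freq_{a}" for a in kept]
    return X, names
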