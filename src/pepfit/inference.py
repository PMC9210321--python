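"""Joint maximum-likelihood inference of lineage fitness and mean fitness.

The model has one (p_i0, omega_i) pair per tracked lineage, a shared
mean-fitness trajectory W_0..W_{T-1} (anchored at W_0 = 1 to fix the
scale invariance (omega, W) -> (c*omega, c*W)), and, for the negative
binomial error model, a single global dispersion kappa. Fitting is block
coordinate ascent:

  (a) per-lineage (p0, omega) by Newton's method in (log p0, log omega),
  (b) W_1..W_{T-1} by quasi-Newton with analytic gradient,

initialized from the analytically tractable Poisson fit and iterated until
the relative change in total log-likelihood drops below ``tol``; the total
log-likelihood is asserted non-decreasing across sweeps. No randomness is
involved anywhere in fitting.

The dispersion kappa is NOT estimated by maximizing the joint likelihood:
with few timepoints, the two mean parameters fitted per lineage absorb
roughly half of the count noise, so the profile likelihood of kappa
degenerates to the Poisson boundary (a textbook incidental-parameters
problem; :func:`profile_kappa` exhibits it). Instead kappa is estimated
from the Pearson dispersion of the fitted residuals with a
degrees-of-freedom correction (quasi-likelihood moment estimator), and
the (p0, omega, W) ascent is re-run at the updated kappa until kappa is
stable.

Standard errors come from the per-lineage 2x2 observed information in the
natural (p0, omega) parameterization, holding the shared (W, kappa) fixed;
downstream regression weights are 1/SE(omega)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .likelihoods import d2loglik_dlam2, dloglik_dlam, loglik
from .types import DispersionParam, Experiment, FitnessFit, MeanFitnessTrajectory

logger = logging.getLogger(__name__)

MAX_SWEEPS = 500
SWEEP_TOL = 1e-10


class LineageFitError(RuntimeError):
    """A per-lineage fit could not be completed (degenerate data or no convergence)."""


@dataclass
class ExperimentFit:
    """Joint fit of an Experiment: per-lineage fits plus shared parameters."""

    fits: list[FitnessFit]
    trajectory: MeanFitnessTrajectory
    dispersion: DispersionParam
    total_loglik: float
    sweeps: int
    converged: bool
    rejected: dict[str, str] = field(default_factory=dict)

    def fit_for(self, peptide_id: str) -> FitnessFit:
        for f in self.fits:
            if f.id == peptide_id:
                return f
        raise KeyError(peptide_id)


def _lam_single(x: np.ndarray, t: np.ndarray, a: np.ndarray) -> np.ndarray:
    # x = (log p0, log omega); lam_t = p0 * omega^t * a_t with a_t = N_t / cumprod(W)
    return np.exp(x[0] + t * x[1]) * a


def fit_lineage(counts, N, W, kappa: float = 1.0):
    """Maximize one lineage's likelihood over (p0, omega) at fixed (W, kappa).

    Returns (p0, omega, loglik). Under the Poisson model the maximum
    satisfies the moment conditions sum(n) = sum(lam) and
    sum(t*n) = sum(t*lam). Lineages with all reads at a single timepoint
    are rejected (fitness is unidentifiable from one day).
    """
    counts = np.asarray(counts, dtype=float)
    N = np.asarray(N, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.count_nonzero(counts) < 1 or np.count_nonzero(counts > 0) == 1:
        raise LineageFitError("all reads at a single timepoint")
    T = len(counts)
    t = np.arange(1, T + 1, dtype=float)
    a = N / np.cumprod(W)
    x = _init_guess(counts, t, a)
    x, ll, ok = _newton_2d(counts, t, a, kappa, x)
    if not ok:
        raise LineageFitError("lineage fit did not converge")
    return float(np.exp(x[0])), float(np.exp(x[1])), ll


def _init_guess(counts: np.ndarray, t: np.ndarray, a: np.ndarray) -> np.ndarray:
    z = np.log((counts + 0.5) / a)
    slope, intercept = np.polyfit(t, z, 1)
    return np.array([np.clip(intercept, -60.0, 0.0), np.clip(slope, -8.0, 8.0)])


def _newton_2d(counts, t, a, kappa, x, max_iter: int = 200, gtol: float = 1e-10):
    """Newton with step-halving in (log p0, log omega). Returns (x, ll, converged)."""
    scale = max(1.0, counts.sum())
    ll = loglik(counts, _lam_single(x, t, a), kappa)
    for _ in range(max_iter):
        lam = _lam_single(x, t, a)
        u = dloglik_dlam(counts, lam, kappa)
        v = d2loglik_dlam2(counts, lam, kappa)
        g = np.array([np.sum(u * lam), np.sum(u * t * lam)])
        if np.max(np.abs(g)) < gtol * scale:
            return x, ll, True
        q = v * lam**2 + u * lam
        H = np.array([[np.sum(q), np.sum(q * t)], [np.sum(q * t), np.sum(q * t**2)]])
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g / scale  # gradient ascent fallback
        if not np.all(np.isfinite(step)):
            step = g / scale
        # step-halving line search on the log-likelihood
        alpha = 1.0
        for _ in range(60):
            x_new = x + alpha * step
            if abs(x_new[1]) < 50 and x_new[0] > -700:
                ll_new = loglik(counts, _lam_single(x_new, t, a), kappa)
                if ll_new >= ll - 1e-13 * abs(ll):
                    x, ll = x_new, ll_new
                    break
            alpha *= 0.5
        else:
            return x, ll, np.max(np.abs(g)) < 1e-6 * scale
    lam = _lam_single(x, t, a)
    u = dloglik_dlam(counts, lam, kappa)
    g = np.array([np.sum(u * lam), np.sum(u * t * lam)])
    return x, ll, np.max(np.abs(g)) < 1e-6 * scale


def fisher_weight(counts, N, W, kappa, p0, omega):
    """Standard error of omega-hat and regression weight from observed information.

    The 2x2 Hessian of the negative log-likelihood in the natural
    (p0, omega) parameterization is inverted at the MLE; se^2 is the omega
    diagonal entry of the inverse and the weight is 1/se^2. A
    non-positive-definite information matrix yields (inf, 0) and the
    lineage should be excluded downstream.
    """
    counts = np.asarray(counts, dtype=float)
    N = np.asarray(N, dtype=float)
    W = np.asarray(W, dtype=float)
    T = len(counts)
    t = np.arange(1, T + 1, dtype=float)
    a = N / np.cumprod(W)
    lam = p0 * omega**t * a
    u = dloglik_dlam(counts, lam, kappa)
    v = d2loglik_dlam2(counts, lam, kappa)
    dl_dp = lam / p0
    dl_dw = t * lam / omega
    H = np.empty((2, 2))
    H[0, 0] = np.sum(v * dl_dp**2)
    H[0, 1] = H[1, 0] = np.sum(v * dl_dp * dl_dw + u * t * lam / (p0 * omega))
    H[1, 1] = np.sum(v * dl_dw**2 + u * t * (t - 1) * lam / omega**2)
    info = -H
    try:
        eigvals = np.linalg.eigvalsh(info)
        if np.min(eigvals) <= 0:
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("inf"), 0.0
    se = float(np.sqrt(cov[1, 1]))
    return se, 1.0 / se**2


def classify_lineage(omega: float, se: float, alpha: float = 0.05) -> str:
    """Wald classification of a lineage against neutrality (omega = 1)."""
    if not np.isfinite(se) or se <= 0:
        return "not_supported"
    z = stats.norm.ppf(1 - alpha / 2)
    if omega - z * se > 1:
        return "increase"
    if omega + z * se < 1:
        return "decrease"
    return "not_supported"


def align_gauge(W_hat, W_ref) -> float:
    """Common factor aligning a fitted trajectory with a reference one.

    Beyond the global scaling handled by the W_0 = 1 anchor, the expected
    reads are exactly invariant under (p0, omega, W_k) ->
    (p0 / c, c * omega, c * W_k for k >= 1), so the absolute level of
    omega and of W_1..W_{T-1} is a reporting convention (a gauge), not an
    estimable quantity. When comparing a fit against an external or true
    trajectory, this returns the factor c = exp(mean over k >= 1 of
    log(W_ref_k / W_hat_k)); multiplying the fitted omega and W_{k>=1} by
    c puts the fit in the reference gauge.
    """
    W_hat = np.asarray(W_hat, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    if len(W_hat) < 2:
        return 1.0
    return float(np.exp(np.mean(np.log(W_ref[1:] / W_hat[1:]))))


def read_filter(counts: np.ndarray, min_reads: int = 5) -> tuple[bool, str]:
    """The study's inclusion rule: >= min_reads total, on >= 2 distinct timepoints."""
    total = int(counts.sum())
    if total < min_reads:
        return False, f"only {total} reads (< {min_reads})"
    if np.count_nonzero(counts > 0) < 2:
        return False, "all reads on the same day"
    return True, ""


def fit_experiment(
    experiment: Experiment,
    min_reads: int = 5,
    model: str = "poisson",
    replicates=None,
    alpha: float = 0.05,
    max_sweeps: int = MAX_SWEEPS,
    tol: float = SWEEP_TOL,
) -> ExperimentFit:
    """Joint MLE over all lineages passing the read filter.

    Replicates are summed before fitting (the expected-read model is
    additive across replicates). The Poisson fit always runs first; for
    ``model="negative_binomial"`` it seeds the NB fit, whose total
    log-likelihood can therefore never fall below the Poisson one when
    kappa-hat > 1.
    """
    if model not in ("poisson", "negative_binomial"):
        raise ValueError(f"unknown model {model!r}")
    exp1 = experiment.summed(replicates)
    counts = exp1.counts[:, :, 0].astype(float)
    N = exp1.totals[:, 0].astype(float)
    T = exp1.n_timepoints

    keep_idx, rejected = [], {}
    for i, pid in enumerate(exp1.peptide_ids):
        ok, reason = read_filter(counts[i], min_reads)
        if ok:
            keep_idx.append(i)
        else:
            rejected[pid] = reason
            logger.info("excluding %s: %s", pid, reason)
    logger.info(
        "read filter: %d of %d lineages kept (min_reads=%d)",
        len(keep_idx), exp1.n_peptides, min_reads,
    )
    if not keep_idx:
        raise ValueError("no lineage passes the read filter")
    ids = [exp1.peptide_ids[i] for i in keep_idx]
    C = counts[keep_idx]

    W = np.ones(T)
    single = len(keep_idx) == 1
    if single:
        logger.warning("single lineage: W is unidentifiable beyond the anchor, fixed at 1")

    state = _sweep(C, N, W, kappa=1.0, fit_W=not single,
                   max_sweeps=max_sweeps, tol=tol)
    kappa, boundary = 1.0, False
    if model == "negative_binomial":
        n_params = 2 * len(keep_idx) + (0 if single else T - 1)
        for _ in range(20):
            kappa_new = pearson_kappa(C, _state_lam(state, N), n_params)
            if abs(kappa_new - kappa) < 1e-6 * max(1.0, kappa):
                kappa = kappa_new
                break
            kappa = kappa_new
            if kappa == 1.0:
                break
            state = _sweep(C, N, state["W"], kappa=kappa, fit_W=not single,
                           max_sweeps=max_sweeps, tol=tol, x0=state["x"])
        if kappa <= 1.0 + 1e-9:
            kappa, boundary = 1.0, True
            logger.info("dispersion at the Poisson boundary; reporting kappa = 1")
        logger.info("kappa = %.4f (Pearson moment estimate)", kappa)

    W = state["W"]
    fits = []
    for j, pid in enumerate(ids):
        p0, omega = np.exp(state["x"][j])
        lam = _lam_single(state["x"][j], np.arange(1, T + 1, dtype=float),
                          N / np.cumprod(W))
        ll_i = loglik(C[j], lam, kappa)
        se, weight = fisher_weight(C[j], N, W, kappa, p0, omega)
        if weight == 0.0:
            logger.info("excluding %s: non-positive-definite information", pid)
        fits.append(
            FitnessFit(
                id=pid, p0=float(p0), omega=float(omega), se=se, weight=weight,
                loglik=ll_i, classification=classify_lineage(omega, se, alpha),
            )
        )
    return ExperimentFit(
        fits=fits,
        trajectory=MeanFitnessTrajectory(W),
        dispersion=DispersionParam(kappa, at_boundary=boundary),
        total_loglik=state["ll"],
        sweeps=state["sweeps"],
        converged=state["converged"],
        rejected=rejected,
    )


def _lam_matrix(x: np.ndarray, t: np.ndarray, a: np.ndarray) -> np.ndarray:
    return np.exp(x[:, [0]] + t[None, :] * x[:, [1]]) * a[None, :]


def _total_loglik(C, x, t, a, kappa) -> float:
    return loglik(C, _lam_matrix(x, t, a), kappa)


def _state_lam(state, N) -> np.ndarray:
    T = len(state["W"])
    t = np.arange(1, T + 1, dtype=float)
    return _lam_matrix(state["x"], t, N / np.cumprod(state["W"]))


def pearson_kappa(C, lam, n_params: int) -> float:
    """Moment estimate of the variance-inflation factor from fitted residuals.

    kappa-hat = sum (n - lam)^2 / lam over all cells, divided by the
    residual degrees of freedom (cells minus fitted mean parameters),
    clamped at the Poisson boundary kappa = 1.
    """
    C = np.asarray(C, dtype=float)
    df = C.size - n_params
    if df <= 0:
        raise ValueError("no residual degrees of freedom to estimate kappa")
    return max(1.0, float(np.sum((C - lam) ** 2 / lam) / df))


def profile_kappa(C, lam) -> float:
    """Joint-likelihood profile estimate of kappa at fixed means (grid + Brent).

    Provided for diagnostics: with few timepoints and per-lineage mean
    parameters fitted to the same data, this estimator is driven to the
    Poisson boundary even on strongly overdispersed counts, which is why
    :func:`fit_experiment` uses :func:`pearson_kappa` instead.
    """

    def negll(s):
        return -loglik(C, lam, 1.0 + np.exp(s))

    grid = np.linspace(-10.0, 5.0, 31)
    vals = [negll(s) for s in grid]
    s_best = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        negll, bounds=(s_best - 1.0, s_best + 1.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return 1.0 + float(np.exp(res.x))


def _sweep(C, N, W0, kappa, fit_W, max_sweeps, tol, x0=None):
    """Block coordinate ascent over per-lineage (p0, omega) and W at fixed kappa."""
    n, T = C.shape
    t = np.arange(1, T + 1, dtype=float)
    W = W0.copy()
    kappa = float(kappa)

    if x0 is None:
        a = N / np.cumprod(W)
        x = np.stack([_init_guess(C[j], t, a) for j in range(n)])
    else:
        x = x0.copy()

    ll_prev = -np.inf
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        a = N / np.cumprod(W)
        for j in range(n):
            x[j], _, ok = _newton_2d(C[j], t, a, kappa, x[j])
            if not ok:
                raise LineageFitError(
                    f"lineage at index {j} failed to converge inside joint fit"
                )
        if fit_W:
            W = _optimize_W(C, N, x, t, W, kappa)
            a = N / np.cumprod(W)
        ll = _total_loglik(C, x, t, a, kappa)
        if ll < ll_prev - 1e-7 * (1.0 + abs(ll_prev)):
            raise RuntimeError(
                f"log-likelihood decreased across sweep {sweeps}: "
                f"{ll_prev} -> {ll}"
            )
        if ll - ll_prev <= tol * (1.0 + abs(ll)):
            converged = True
            ll_prev = max(ll, ll_prev)
            break
        ll_prev = ll
    # final lineage pass at the final W so the per-lineage score equations
    # hold exactly at the returned parameters
    a = N / np.cumprod(W)
    for j in range(n):
        x[j], _, _ = _newton_2d(C[j], t, a, kappa, x[j])
    ll_final = _total_loglik(C, x, t, a, kappa)
    return {"x": x, "W": W, "kappa": kappa, "ll": max(ll_final, ll_prev),
            "sweeps": sweeps, "converged": converged}


def _optimize_W(C, N, x, t, W, kappa) -> np.ndarray:
    """Maximize the total log-likelihood over log W_1..log W_{T-1} (W_0 = 1)."""
    T = len(W)
    u_cols = np.arange(T)

    def negll_and_grad(z):
        W_full = np.concatenate([[1.0], np.exp(z)])
        a = N / np.cumprod(W_full)
        lam = _lam_matrix(x, t, a)
        u = dloglik_dlam(C, lam, kappa)
        # W_k enters lam columns t >= k+1 (0-based columns j >= k) with power -1
        grad = np.array(
            [np.sum(u[:, u_cols >= k] * lam[:, u_cols >= k]) for k in range(1, T)]
        )
        return -loglik(C, lam, kappa), grad

    res = optimize.minimize(
        negll_and_grad, np.log(W[1:]), jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-9},
    )
    W_new = np.concatenate([[1.0], np.exp(res.x)])
    # keep the better of old/new so the sweep stays monotone
    a_old, a_new = N / np.cumprod(W), N / np.cumprod(W_new)
    if loglik(C, _lam_matrix(x, t, a_new), kappa) >= loglik(
        C, _lam_matrix(x, t, a_old), kappa
    ):
        return W_new
    return W.copy()
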