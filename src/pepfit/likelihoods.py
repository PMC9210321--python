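"""Read-count likelihoods for the growth-dilution competition model.

A lineage i with fitness omega_i starting at frequency p_i0 is expected to
yield

    lambda_it = N_t * p_i0 * prod_{k=1..t} (omega_i / W_{k-1})

reads at timepoint t, where N_t is the total sequencing depth and W_k the
population mean fitness during cycle k (including untagged empty-vector
cells, so it is a free parameter rather than an average over tracked
lineages). Counts are modelled as Poisson(lambda) or, to absorb PCR
variance inflation kappa, as a negative binomial in the Polya form with
size r = lambda/(kappa-1) and success probability 1/kappa, which has mean
lambda and variance kappa*lambda.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def expected_reads(p0: float, omega: float, W, N) -> np.ndarray:
    """Expected reads lambda_t for t = 1..T.

    Parameters
    ----------
    p0 : initial lineage frequency, in (0, 1).
    omega : lineage fitness per growth-dilution cycle, > 0.
    W : mean-fitness trajectory W_0..W_{T-1}, all > 0.
    N : total reads N_1..N_T, all > 0.
    """
    W = np.asarray(W, dtype=float)
    N = np.asarray(N, dtype=float)
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    if np.any(W <= 0):
        raise ValueError("all W_k must be positive")
    if np.any(N <= 0):
        raise ValueError("all N_t must be positive")
    if len(W) != len(N):
        raise ValueError("W and N must have length T")
    t = np.arange(1, len(N) + 1)
    cumW = np.cumprod(W)  # cumW[t-1] = W_0 * ... * W_{t-1}
    return N * p0 * omega**t / cumW


def poisson_loglik(n, lam) -> float:
    """Sum over timepoints of the Poisson log-pmf of counts n at means lam."""
    n = np.asarray(n)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    return float(stats.poisson.logpmf(n, lam).sum())


def nb_polya_loglik(n, lam, kappa: float) -> float:
    """Negative-binomial (Polya form) log-likelihood summed over timepoints.

    Size r = lam/(kappa-1), success probability 1/kappa; mean lam and
    variance kappa*lam. kappa = 1 dispatches to the Poisson limit.
    """
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1, got {kappa}")
    if kappa == 1:
        return poisson_loglik(n, lam)
    n = np.asarray(n)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    eps = kappa - 1.0
    if eps < 1e-6:
        # near the Poisson limit the direct pmf loses precision (gammaln of
        # huge size parameters); use the first-order expansion in kappa - 1
        correction = eps * ((n - lam) ** 2 - n) / (2.0 * lam)
        return poisson_loglik(n, lam) + float(correction.sum())
    r = lam / eps
    return float(stats.nbinom.logpmf(n, r, 1.0 / kappa).sum())


def loglik(n, lam, kappa: float) -> float:
    return nb_polya_loglik(n, lam, kappa) if kappa > 1 else poisson_loglik(n, lam)


def dloglik_dlam(n, lam, kappa: float) -> np.ndarray:
    """First derivative of the per-timepoint log-pmf with respect to lambda."""
    n = np.asarray(n, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if kappa - 1.0 < 1e-6:
        return n / lam - 1.0
    r = lam / (kappa - 1.0)
    return (special.digamma(n + r) - special.digamma(r) - np.log(kappa)) / (kappa - 1.0)


def d2loglik_dlam2(n, lam, kappa: float) -> np.ndarray:
    """Second derivative of the per-timepoint log-pmf with respect to lambda."""
    n = np.asarray(n, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if kappa - 1.0 < 1e-6:
        return -n / lam**2
    r = lam / (kappa - 1.0)
    return (special.polygamma(1, n + r) - special.polygamma(1, r)) / (kappa - 1.0) ** 2
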