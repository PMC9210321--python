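"""Marginal fitness effects of individual amino acids.

In a fixed-length peptide one residue cannot be gained without another
being lost, so the raw regression coefficient on a residue's frequency is
not interpretable on its own. The marginal effect of residue j is instead
defined as the predicted fitness of a baseline-composition peptide after
ONE residue of the focal type replaces one randomly chosen residue of a
different type:

    effect_j = F_bar + (1/L) * (beta_j - sum_{a != j} pi_a^(-j) * beta_a)

where F_bar is the model prediction at the (weight-weighted) baseline
composition f_bar, L is the random-region length, and
pi_a^(-j) = f_bar_a / (1 - f_bar_j) is the probability that the randomly
removed residue is of type a. Coefficients live on a common 20-vector
scale with the regression's dropped column restored at 0; because
sum_a pi_a^(-j) = 1, the effects are invariant to which column was
dropped. Standard errors come from the delta method on the coefficient
covariance, treating f_bar as fixed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import AMINO_ACIDS, CompositionRecord, MarginalEffect, RegressionFit


def baseline_composition(
    comps: Sequence[CompositionRecord], weights: Sequence[float]
) -> np.ndarray:
    """Weight-weighted mean amino-acid frequency vector (sums to 1)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    F = np.stack([c.freq_vector() for c in comps])
    return np.average(F, axis=0, weights=weights)


def _coef_layout(fit: RegressionFit) -> tuple[int, dict[str, int]]:
    """Locate the intercept and freq_<residue> coefficients in a fit."""
    if "intercept" not in fit.names:
        raise ValueError("fit must contain an 'intercept' coefficient")
    icpt = fit.names.index("intercept")
    res_idx = {}
    for i, name in enumerate(fit.names):
        if name.startswith("freq_"):
            res = name[len("freq_"):]
            if res not in AMINO_ACIDS:
                raise ValueError(f"unknown residue column {name!r}")
            res_idx[res] = i
    if not res_idx:
        raise ValueError("fit has no freq_<residue> columns")
    return icpt, res_idx


def marginal_effects(
    fit: RegressionFit, f_bar: np.ndarray, L: int
) -> list[MarginalEffect]:
    """Marginal fitness effect (+ delta-method SE) for each of the 20 residues."""
    f_bar = np.asarray(f_bar, dtype=float)
    icpt, res_idx = _coef_layout(fit)
    out = []
    for j, res_j in enumerate(AMINO_ACIDS):
        if f_bar[j] >= 1.0:
            raise ValueError(
                f"baseline composition is pure {res_j}; substitution undefined"
            )
        # gradient of effect_j with respect to the fitted coefficient vector
        c = np.zeros(len(fit.coefficients))
        c[icpt] = 1.0
        for a, res_a in enumerate(AMINO_ACIDS):
            if res_a not in res_idx:
                continue  # dropped column: beta fixed at 0
            k = res_idx[res_a]
            c[k] += f_bar[a]  # F_bar term
            if res_a == res_j:
                c[k] += 1.0 / L
            else:
                c[k] -= f_bar[a] / (1.0 - f_bar[j]) / L
        effect = float(c @ fit.coefficients)
        se = float(np.sqrt(c @ fit.covariance @ c))
        out.append(
            MarginalEffect(residue=res_j, effect=effect, se=se, weight=1.0 / se**2)
        )
    return out


def predict_fitness(fit: RegressionFit, composition) -> float:
    """Predicted fitness of an arbitrary composition under the frequency model.

    ``composition`` is a residue -> frequency mapping, a CompositionRecord,
    or a 20-vector in canonical residue order; frequencies must sum to 1.
    """
    if isinstance(composition, CompositionRecord):
        freqs = composition.freq_vector()
    elif isinstance(composition, dict):
        unknown = sorted(set(composition) - set(AMINO_ACIDS))
        if unknown:
            raise ValueError(f"unknown residues in composition: {unknown}")
        freqs = np.array([composition.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    else:
        freqs = np.asarray(composition, dtype=float)
        if freqs.shape != (20,):
            raise ValueError("composition vector must have length 20")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("composition frequencies must sum to 1")
    icpt, res_idx = _coef_layout(fit)
    value = fit.coefficients[icpt]
    for res, k in res_idx.items():
        value += fit.coefficients[k] * freqs[AMINO_ACIDS.index(res)]
    return float(value)
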