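"""End-to-end analysis of fitted, clustered peptide data.

Ties the stages together: cluster-collapsed pseudo-datapoints feed
weighted fixed-effect regressions of fitness on composition predictors
(amino-acid frequencies, GC content, property-scale averages), marginal
amino-acid effects with their property correlations, and the GC
constraint-class comparisons. The output is a plain dict ready to be
serialized as the analysis report JSON.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .clustering import collapse_clusters, single_link_clusters
from .composition import aa_composition, codon_constraint_classes
from .inference import ExperimentFit
from .marginal import baseline_composition, marginal_effects
from .stats import (
    aa_frequency_design,
    lrt,
    quantile_effect_size,
    weighted_pearson,
    weighted_welch_ttest,
    wls_fit,
)
from .types import AMINO_ACIDS, Cluster, CompositionRecord, PeptideRecord, PropertyScale

logger = logging.getLogger(__name__)


def cluster_pseudo_data(
    records: Sequence[PeptideRecord],
    fit: ExperimentFit,
    cutoff: int = 6,
    mode: str = "weighted_mean",
) -> tuple[list[Cluster], list[CompositionRecord], np.ndarray, np.ndarray]:
    """Cluster fitted peptides and collapse to pseudo-datapoints.

    Returns (clusters, representative compositions, fitness vector,
    weight vector) aligned by cluster. The composition attached to a
    cluster is that of its highest-weight member, as is its GC content.
    """
    fits = {f.id: f for f in fit.fits if f.weight > 0}
    by_id = {r.id: r for r in records}
    fitted = [(pid, by_id[pid].aa_seq) for pid in fits if pid in by_id]
    clusters = collapse_clusters(single_link_clusters(fitted, cutoff), fits, mode)
    comps = [aa_composition(by_id[cl.representative]) for cl in clusters]
    y = np.array([cl.pseudo_fitness for cl in clusters])
    w = np.array([cl.pseudo_weight for cl in clusters])
    return clusters, comps, y, w


def aa_frequency_model(
    comps: Sequence[CompositionRecord], y: np.ndarray, w: np.ndarray, drop: str = "A"
):
    """Weighted regression of fitness on 19 amino-acid frequency columns.

    Returns (fit, intercept-only null fit, LRT against the null).
    """
    X, names = aa_frequency_design(comps, drop=drop)
    full = wls_fit(X, y, w, names=names)
    null = wls_fit(np.ones((len(y), 1)), y, w, names=["intercept"])
    return full, null, lrt(null, full)


def single_predictor_model(x: np.ndarray, y: np.ndarray, w: np.ndarray, name: str):
    """Weighted regression of fitness on one predictor, with LRT and effect size."""
    X = np.column_stack([np.ones(len(y)), x])
    fit = wls_fit(X, y, w, names=["intercept", name])
    null = wls_fit(np.ones((len(y), 1)), y, w, names=["intercept"])
    test = lrt(null, fit)
    lo, hi = quantile_effect_size(fit, x, w)
    return {
        "predictor": name,
        "slope": float(fit.coefficients[1]),
        "r2_adj": fit.r2_adj,
        "lrt_p": test.p_value,
        "effect_10_90": [lo, hi],
        "fit": fit,
    }


def marginal_effect_block(
    fit, comps, w, region_length: int, scales: Sequence[PropertyScale]
) -> dict:
    """Marginal effects plus their weighted correlations with property scales
    and the codon-position GC/AT constraint-class comparisons."""
    f_bar = baseline_composition(comps, w)
    effects = marginal_effects(fit, f_bar, region_length)
    eff = np.array([e.effect for e in effects])
    ew = np.array([e.weight for e in effects])
    out = {
        "effects": {e.residue: {"effect": e.effect, "se": e.se} for e in effects},
        "scale_correlations": {},
        "gc_constraint_tests": {},
    }
    for scale in scales:
        res = weighted_pearson(scale.as_vector(), eff, ew)
        out["scale_correlations"][scale.name] = {"r": res.r, "p": res.p_value}
    for position in (1, 2):
        classes = codon_constraint_classes(position)
        gc_idx = [i for i, a in enumerate(AMINO_ACIDS) if a in classes.always_gc]
        at_idx = [i for i, a in enumerate(AMINO_ACIDS) if a in classes.always_at]
        if len(gc_idx) >= 2 and len(at_idx) >= 2:
            res = weighted_welch_ttest(eff[gc_idx], ew[gc_idx], eff[at_idx], ew[at_idx])
            out["gc_constraint_tests"][f"position_{position}"] = {
                "t": res.t, "df": res.df, "p": res.p_value,
                "n_always_gc": len(gc_idx), "n_always_at": len(at_idx),
            }
    return out


def gc_split_models(comps, y, w, drop: str = "A") -> dict:
    """Refit the frequency model separately above/below the weighted median GC."""
    gc = np.array([c.gc for c in comps])
    from .stats import weighted_quantile

    median = weighted_quantile(gc, w, 0.5)
    out = {"gc_median": float(median)}
    for label, mask in (("high", gc > median), ("low", gc <= median)):
        X, names = aa_frequency_design([c for c, m in zip(comps, mask) if m], drop=drop)
        if mask.sum() <= X.shape[1]:
            logger.warning("GC split %s side too small to fit (n=%d)", label, mask.sum())
            continue
        fit = wls_fit(X, y[mask], w[mask], names=names)
        out[label] = {"n": int(mask.sum()), "r2_adj": fit.r2_adj}
    return out


def run_analysis(
    records: Sequence[PeptideRecord],
    fit: ExperimentFit,
    cutoff: int = 6,
    scales: Optional[Sequence[PropertyScale]] = None,
    drop: str = "A",
) -> dict:
    """The full downstream analysis on a fitted experiment; returns the report dict."""
    from .composition import annotate_scale_means
    from .io import BUNDLED_SCALES, bundled_scale

    if scales is None:
        scales = [bundled_scale(n) for n in BUNDLED_SCALES]
    clusters, comps, y, w = cluster_pseudo_data(records, fit, cutoff)
    annotate_scale_means(comps, list(scales))
    region_length = comps[0].region_length

    full, null, aa_test = aa_frequency_model(comps, y, w, drop=drop)
    gc = np.array([c.gc for c in comps])
    gc_block = single_predictor_model(gc, y, w, "gc")
    scale_blocks = {
        s.name: single_predictor_model(
            np.array([c.scale_means[s.name] for c in comps]), y, w, s.name
        )
        for s in scales
    }

    classifications = [f.classification for f in fit.fits]
    report = {
        "n_peptides_fit": len(fit.fits),
        "n_clusters": len(clusters),
        "largest_cluster": max(len(c.members) for c in clusters),
        "classification_counts": {
            c: classifications.count(c) for c in ("increase", "decrease", "not_supported")
        },
        "kappa": fit.dispersion.kappa,
        "W": [float(x) for x in fit.trajectory.W],
        "aa_frequency_model": {
            "r2": full.r2, "r2_adj": full.r2_adj,
            "lrt_p": aa_test.p_value, "n": full.n, "p": full.p,
        },
        "gc_model": {k: v for k, v in gc_block.items() if k != "fit"},
        "gc_split": gc_split_models(comps, y, w, drop=drop),
        "scale_models": {
            name: {k: v for k, v in blk.items() if k != "fit"}
            for name, blk in scale_blocks.items()
        },
        "marginal": marginal_effect_block(full, comps, w, region_length, list(scales)),
        "mean_cluster_gc": float(np.mean(gc)),
    }
    return report
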