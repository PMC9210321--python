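# Methods

## The count model

A pooled competition tracks lineages over T growth-dilution cycles
(T = 4 by default, matching a four-day serial-passage design). Lineage
*i* has an initial frequency `p_i0` and a fitness `omega_i`, defined as
the multiplicative change in its frequency per whole cycle — not per
generation, since the number of generations per cycle is neither constant
nor observed. The population mean fitness during cycle *k*, `W_k`,
includes untagged empty-vector cells for which no reads exist, so it
cannot be computed as an average over tracked lineages and is fitted as a
free parameter per cycle. The expected reads are

    lambda_it = N_t * p_i0 * prod_{k=1..t} (omega_i / W_{k-1}),

and observed counts are Poisson(lambda) or, to absorb PCR amplification
noise, Polya-form negative binomial with size `lambda/(kappa-1)` and
success probability `1/kappa` (mean `lambda`, variance `kappa*lambda`;
`kappa = 1` recovers Poisson). Near the Poisson limit
(`kappa - 1 < 1e-6`) the NB log-pmf is evaluated by a first-order
expansion in `kappa - 1`, because the direct form loses precision through
gammaln of enormous size parameters.

Replicates are summed before fitting: the expected-read model is additive
across replicates with a shared `(p_i0, omega_i)`, so pooling loses
nothing at the point-estimate level. Any replicate subset can be selected.

## Identifiability and the reporting gauge

Two exact invariances constrain what the data can determine:

1. `W_0` is completely confounded with the `p_i0` (both enter each
   lineage's expected reads as a single multiplicative constant). The fit
   anchors `W_0 = 1`.
2. Less obviously, `(p_i0, omega_i, W_k) -> (p_i0/c, c*omega_i, c*W_k
   for k >= 1)` leaves every `lambda_it` unchanged: the cumulative
   log-trajectory is identified only up to its linear-in-t component,
   which per-lineage `(log p_i0, log omega_i)` absorb. The *absolute
   level* of fitness is therefore a reporting convention (a gauge), while
   fitness *ratios* between lineages, the curvature of `W`, and `kappa`
   are genuinely estimable. This caveat is intrinsic to the model, not to
   the optimizer.

The fitter reports the gauge its deterministic initialization
(`W = 1` everywhere, Poisson moment start) converges to. When a fit must
be compared against an external or simulated truth, `align_gauge`
estimates the single common factor from the trajectory comparison and
puts estimates in the reference gauge; the recovery tests and the
acceptance script do exactly that before measuring coverage or trajectory
error. Classifications of individual lineages against neutrality inherit
the gauge; under the default conditions the gauge factor is within a few
percent of one, and the all-neutral simulation (where the truth lies in
the fitted gauge) shows the Wald classification holds its nominal error
rate.

## Fitting

Block coordinate ascent on the total log-likelihood:

- per lineage, Newton's method with step-halving in
  `(log p_0, log omega)` (closed-form 2x2 solves; the Poisson MLE
  satisfies the moment conditions `sum n = sum lambda` and
  `sum t*n = sum t*lambda` to the Newton tolerance);
- `W_1..W_{T-1}` by L-BFGS-B in log space with the analytic gradient,
  keeping the previous value if the step does not improve the likelihood;
- sweeps repeat until the relative log-likelihood change is below 1e-10
  (cap 500), with monotonicity asserted each sweep, followed by one final
  per-lineage pass at the final `W` so the score equations hold exactly
  at the returned parameters.

No randomness enters the fit anywhere.

**Dispersion.** `kappa` is *not* profiled on the joint likelihood: with
T = 4 observations and two mean parameters per lineage, the fitted means
absorb roughly half the count noise, and the profile likelihood of
`kappa` is maximized at the Poisson boundary even on strongly
overdispersed data (the incidental-parameters problem; the degenerate
estimator is kept as `profile_kappa` for diagnostics). Instead `kappa` is
the Pearson moment estimate — the residual chi-square over all cells
divided by the residual degrees of freedom (cells minus 2 per lineage
minus T-1 for the trajectory) — iterated with the coordinate ascent until
stable, and clamped at the boundary `kappa = 1` (reported with a boundary
flag). This is the standard quasi-likelihood treatment of a dispersion
parameter and recovers the simulated inflation within a few percent at
study-like depth. A consequence is that the NB likelihood at the reported
`kappa` is *below* the Poisson likelihood — the moment estimate trades
likelihood for consistency.

**Standard errors.** The per-lineage 2x2 observed information in the
natural `(p_0, omega)` parameterization is inverted at the MLE, holding
the shared `(W, kappa)` fixed (each lineage contributes a vanishing
fraction of the information about the shared parameters). `SE(omega)` is
on the fitness scale, since downstream weights are defined as
`1/SE(fitness)^2`. A non-positive-definite information matrix yields
weight 0 and the lineage is excluded from weighted analyses.

**Filters and classification.** Lineages enter the fit with at least
`min_reads` (default 5) summed reads on at least two distinct timepoints;
all-reads-on-one-day lineages are excluded as fitness-uninformative.
Classification is a two-sided Wald test against `omega = 1` at
`alpha = 0.05`.

## Clustering

Peptides a few substitutions apart are pseudoreplicates. Single-link
clustering merges peptides connected by chains of Hamming distance <=
cutoff (default 6), computed on the full amino-acid sequence including
non-random flanks, via union-find with deterministic output order. Each
cluster is collapsed to one pseudo-datapoint: weighted-mean fitness with
weight equal to the summed member weights (or, alternatively, the
highest-weight member's values; ties broken by smallest id). Because a
random 50-residue region makes unrelated peptides differ at ~47
positions while mutants differ at 1-2, the partition is flat over a wide
cutoff window — the planted-cluster tests assert identical partitions
across cutoffs 4..29.

## Composition predictors

Amino-acid counts and frequencies are taken over the random region only.
GC content is the unweighted mean over all nucleotide variants mapping to
a peptide, random region only; a cluster's GC is that of its
highest-weight member. Property-scale averages (volume, TOP-IDP disorder
propensity, E. coli synthesis cost, stickiness, maximum solvent
accessibility, isoelectric point; bundled as versioned CSVs with sources
in the file headers) are frequency-weighted means over the region.
Precomputed whole-construct scores from external sequence predictors can
be ingested from TSV with an optional square-root transform; the
region-only vs whole-construct distinction between the two score families
is deliberate and configurable. Codon-position GC/AT constraint classes
and codon-number expected frequencies (e.g. 3/61 for isoleucine) are
enumerated from the 61 sense codons of the standard genetic code.

## Weighted statistics

All statistics treat weights as relative precisions and are invariant
under rescaling all weights by a constant. Weighted least squares is
delegated to statsmodels (coefficients, `sigma^2 (X'WX)^{-1}` covariance,
Gaussian log-likelihood); adjusted R-squared uses
`1 - (1 - R^2)(n-1)/(n-p-1)` with p the predictor count. The amino-acid
frequency model drops one residue column (alanine by default) because the
20 frequencies sum to one; marginal effects are provably invariant to
which column is dropped, and a test asserts it. Likelihood-ratio tests
compare nested fits on identical responses and weights against the
chi-square; raw p-values are reported, two-sided, without
multiple-testing correction. A single-random-intercept ML fit (variance
ratio profiled with per-group Woodbury identities) is provided as a
cross-check on the cluster-collapsed fixed-effect path; the collapsed
fixed-effect model remains the canonical analysis, and no numeric parity
with any external mixed-model implementation is claimed. The weighted
Pearson correlation uses the nonzero-weight count as its effective sample
size; the weighted Welch t-test normalizes weights within each group to
the group size before applying the Welch-Satterthwaite machinery;
weighted quantiles place observations at midpoint cumulative weights with
linear interpolation, reducing exactly to type-7 quantiles under equal
weights.

## Marginal effects

The marginal effect of residue j is the predicted fitness of a
baseline-composition peptide after one residue of the focal type replaces
one randomly chosen residue of a *different* type:

    effect_j = F_bar + (1/L) * (beta_j - sum_{a != j} pi_a^(-j) beta_a),
    pi_a^(-j) = f_bar_a / (1 - f_bar_j),

with `F_bar` the model prediction at the weight-weighted mean composition
`f_bar`, L the region length (50), and coefficients on a common 20-vector
scale (dropped column at 0). Because the removed residue is conditioned
on being a different type, the substitution never degenerates to a no-op;
`f_bar_j = 1` is rejected. Standard errors are delta-method on the
coefficient covariance with `f_bar` treated as fixed — its sampling noise
is second-order at hundreds of clusters. `predict_fitness` applies the
same coefficients to arbitrary compositions (e.g. external tag sets).

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, and
its defaults are the package's reference study conditions:

- ORFs: 50 random codons between fixed flanks (65 aa total), nucleotides
  i.i.d. with P(G) = P(C) = gc_target/2 (default 0.5, the library-design
  value; stop codons redrawn, which raises realized GC by ~1.4 points at
  the 0.5 target);
- true fitness `1 + sum_a effect_a * freq_a + N(0, noise_sd)`, truncated
  at 0.01; the default effect vector is a standardized
  disorder-minus-volume gradient scaled to across-residue SD 2.0 with
  mean -0.25, giving peptide fitness mean ~0.75 and SD ~0.3 — deleterious
  on average with a broad spread, echoing a random-peptide pool in which
  most inserts are somewhat harmful, with default observation noise
  SD 0.05;
- dynamics: one multiplicative update per cycle, `p <- p * omega / W`,
  with the empty-vector pool (initial fraction 0.5, fitness 1.0) as a
  single mega-lineage inside `W` that never yields reads; totals are the
  full sequencing depth (default 1e5 reads per timepoint, giving ~100
  reads/lineage/timepoint at n = 500 — the depth regime where recovery is
  informative yet nontrivial);
- reads Poisson or Polya-NB per timepoint and replicate; planted
  near-duplicate clusters add 2-5 mutants at amino-acid Hamming distance
  1-2, mutated at the codon level so nucleotide and protein sequences
  stay consistent.

One `numpy` Generator seeded once per call drives all randomness.

What the generator does *not* emulate — and what passing recovery tests
therefore cannot certify on real data: mutation during growth, PCR
chimeras, base-level sequencing error, GC-dependent sequencing bias,
lineage extinction/bottleneck stochasticity beyond read sampling, and
auto-downregulation of expression at the RNA level. The composition-
linear fitness map is the model's own assumption; real peptides can
violate it through order-dependent effects.

## Numerical choices and degenerate inputs

- Lineage Newton: convergence at gradient < 1e-10 x total reads, 200
  iterations, 60 step-halvings; failures raise rather than silently pass.
- `W` step: L-BFGS-B, ftol 1e-14; rejected if it does not improve.
- Problem sizes in tests and the acceptance script (500 lineages, depth
  1e5, 200-peptide clustering oracles, 1000-replicate LRT null) were
  chosen so each check is statistically decisive at desk scale.
- Degenerate cases: single lineage fixes `W = 1` with a warning;
  single-group random-intercept falls back to WLS; identical-model LRT
  returns p = 1; all-equal-value Welch groups return t = 0, p = 1 with a
  degenerate flag; all-zero-weight clusters are dropped with a log entry.

## Known limitations

- The fitness scale is a gauge (see above); cross-experiment comparisons
  of absolute omega require an external convention.
- The Pearson `kappa` is slightly upward-biased (a few percent at the
  default depth) because residual leverage is approximated by a global
  degrees-of-freedom correction.
- The random-intercept fit supports exactly one variance component.
- Clustering is O(n^2) in the number of fitted peptides — fine for the
  10^3 scale it is designed for, not for raw-library scale.
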