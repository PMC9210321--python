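"""Core value types shared across the pipeline.

All sequence intervals are 1-based inclusive on the amino-acid sequence;
nucleotide coordinates of a region are three times the amino-acid
coordinates. Timepoints are 1-based integers t = 1..T, while the mean
population fitness trajectory is indexed W_0..W_{T-1} (W_k applies to the
growth-dilution cycle that produces timepoint k+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical amino acids in alphabetical one-letter order. This ordering is
#: used for every frequency vector in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class Experiment:
    """Read counts per tracked peptide lineage per timepoint per replicate.

    ``counts[i, t-1, r]`` is the number of reads of peptide ``peptide_ids[i]``
    at timepoint ``t`` in replicate ``r``; ``totals[t-1, r]`` is the total
    number of reads sequenced at that timepoint/replicate (tracked lineages
    are in general a small subset of the library, so column sums of
    ``counts`` are at most ``totals``).
    """

    peptide_ids: list[str]
    counts: np.ndarray  # (n_peptides, T, n_replicates), non-negative ints
    totals: np.ndarray  # (T, n_replicates), positive ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, :, None]
        if self.totals.ndim == 1:
            self.totals = self.totals[:, None]
        if self.counts.shape[0] != len(self.peptide_ids):
            raise ValueError("counts first axis must match peptide_ids")
        if self.counts.shape[1:] != self.totals.shape:
            raise ValueError("counts (T, replicates) axes must match totals")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.totals <= 0):
            raise ValueError("totals must be positive")
        colsums = self.counts.sum(axis=0)
        if np.any(colsums > self.totals):
            raise ValueError(
                "totals must be at least the column sums of tracked counts"
            )

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]

    def summed(self, replicates: Optional[list[int]] = None) -> "Experiment":
        """Sum counts and totals across a replicate subset (default: all).

        Replicates behave additively under the read-count model, so pooling
        them is done by plain summation before fitting.
        """
        if replicates is None:
            replicates = list(range(self.n_replicates))
        c = self.counts[:, :, replicates].sum(axis=2, keepdims=True)
        n = self.totals[:, replicates].sum(axis=1, keepdims=True)
        return Experiment(list(self.peptide_ids), c, n)


@dataclass
class PeptideRecord:
    """A peptide with one amino-acid sequence and >= 1 nucleotide variants.

    ``random_region`` delimits the randomized part of the amino-acid
    sequence (1-based inclusive). Every nucleotide variant must translate to
    ``aa_seq`` under the standard genetic code with no internal stops.
    """

    id: str
    aa_seq: str
    nt_variants: list[str]
    random_region: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.random_region
        if not (1 <= lo <= hi <= len(self.aa_seq)):
            raise ValueError(
                f"random_region {self.random_region} out of bounds for "
                f"{self.id} (length {len(self.aa_seq)})"
            )
        bad = set(self.aa_seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in {self.id}: {sorted(bad)}")

    @property
    def region_aa(self) -> str:
        lo, hi = self.random_region
        return self.aa_seq[lo - 1 : hi]

    @property
    def region_nt_interval(self) -> tuple[int, int]:
        lo, hi = self.random_region
        return 3 * (lo - 1) + 1, 3 * hi

    def region_nt(self, variant: str) -> str:
        lo, hi = self.region_nt_interval
        if len(variant) < hi:
            raise ValueError(
                f"nucleotide variant of {self.id} shorter than its random region"
            )
        return variant[lo - 1 : hi]


@dataclass
class PropertyScale:
    """A named per-residue property (volume, disorder propensity, ...)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r}: missing residues {missing}, "
                f"unknown residues {extra}"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


@dataclass
class MeanFitnessTrajectory:
    """Population mean fitness per cycle, anchored at W_0 = 1."""

    W: np.ndarray  # (T,), positive, W[0] == 1 after fitting

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.W <= 0):
            raise ValueError("all W_k must be positive")


@dataclass
class DispersionParam:
    """Variance-inflation factor: Var(reads) = kappa * mean. kappa = 1 is Poisson."""

    kappa: float
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass
class FitnessFit:
    """Per-lineage maximum-likelihood fit and Wald classification."""

    id: str
    p0: float
    omega: float
    se: float
    weight: float
    loglik: float
    classification: str = "not_supported"

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se > 0:
            if not np.isclose(self.weight * self.se**2, 1.0):
                raise ValueError("weight must equal 1/se^2")


@dataclass
class Cluster:
    """A single-link cluster of near-duplicate peptides.

    The pseudo-datapoint (weighted-mean fitness, summed weight) stands in
    for the cluster in downstream fixed-effect regressions, avoiding
    pseudoreplication.
    """

    members: list[str]
    representative: str
    pseudo_fitness: float = np.nan
    pseudo_weight: float = np.nan

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass
class CompositionRecord:
    """Amino-acid composition of a peptide's random region."""

    id: str
    aa_counts: dict[str, int]
    region_length: int
    gc: float = np.nan
    scale_means: dict[str, float] = field(default_factory=dict)

    @property
    def aa_freqs(self) -> dict[str, float]:
        return {a: c / self.region_length for a, c in self.aa_counts.items()}

    def freq_vector(self) -> np.ndarray:
        return np.array(
            [self.aa_counts.get(a, 0) / self.region_length for a in AMINO_ACIDS]
        )


@dataclass
class CodonConstraintClasses:
    """Partition of residues by GC/AT constraint at one codon position."""

    position: int
    always_gc: frozenset[str]
    always_at: frozenset[str]
    mixed: frozenset[str]

    def __post_init__(self) -> None:
        union = self.always_gc | self.always_at | self.mixed
        total = len(self.always_gc) + len(self.always_at) + len(self.mixed)
        if union != set(AMINO_ACIDS) or total != 20:
            raise ValueError("constraint classes must partition the 20 residues")


@dataclass
class MarginalEffect:
    """Predicted fitness after one random-to-focal substitution."""

    residue: str
    effect: float
    se: float
    weight: float

    def __post_init__(self) -> None:
        if self.se > 0 and not np.isclose(self.weight * self.se**2, 1.0):
            raise ValueError("weight must equal 1/se^2")


@dataclass
class RegressionFit:
    """A weighted linear model fit (coefficients in response units per predictor unit)."""

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    r2: float
    r2_adj: float
    n: int
    p: int
    names: list[str] = field(default_factory=list)
    y: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None
    sigma2: float = np.nan
    group_var: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients
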