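"""Synthetic peptide libraries and count time series.

The generator emulates the statistical structure the inference assumes: a
library of fixed-length open reading frames with a randomized region of
controllable GC content, composition-linear true fitness, an untagged
empty-vector pool that contributes to population mean fitness but never to
reads, growth-dilution frequency dynamics collapsed to one multiplicative
update per timepoint, and Poisson or Polya-form negative-binomial read
sampling with variance inflation kappa. Planted near-duplicate clusters
provide ground truth for the clustering stage.

All randomness flows from a single numpy Generator seeded once per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .composition import aa_composition
from .io import bundled_scale
from .types import AMINO_ACIDS, Experiment, PeptideRecord

logger = logging.getLogger(__name__)

#: Fixed flanking sequences: 8 aa N-terminal (with start codon) and 7 aa
#: C-terminal, so a 50-aa random region yields the study-like 65-aa peptide.
FLANK5_NT = "ATGGCGAGCAAAGGCGAAGAACTG"  # MASKGEEL
FLANK3_NT = "GGTTCTGGCAGCCATCATCAT"  # GSGSHHH

STOP_CODONS = ("TAA", "TAG", "TGA")


def default_true_effects(spread: float = 2.0, offset: float = -0.25) -> dict[str, float]:
    """Composition effects planted by default: a size/disorder gradient.

    Built from the bundled volume and disorder-propensity scales
    (standardized, disorder minus volume), rescaled to a chosen
    across-residue standard deviation and mean. With the defaults, peptide
    true fitness has mean ~0.75 and SD ~0.3 — deleterious on average with
    a broad spread, echoing a pooled competition in which most random
    peptides are somewhat harmful.
    """
    vol = bundled_scale("volume").as_vector()
    dis = bundled_scale("disorder_propensity").as_vector()
    raw = (dis - dis.mean()) / dis.std() - (vol - vol.mean()) / vol.std()
    eff = raw / raw.std() * spread + offset
    return dict(zip(AMINO_ACIDS, eff))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study conditions."""

    n_lineages: int = 500
    region_len_aa: int = 50
    gc_target: float = 0.5
    true_effects: dict[str, float] = field(default_factory=default_true_effects)
    noise_sd: float = 0.05
    empty_fraction0: float = 0.5
    empty_fitness: float = 1.0
    depth: int = 100_000
    T: int = 4
    kappa: float = 1.0
    n_replicates: int = 1
    n_duplicate_clusters: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gc_target <= 1 and 0 <= self.empty_fraction0 < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.depth <= 0 or self.kappa < 1 or self.T < 2:
            raise ValueError("need depth > 0, kappa >= 1, T >= 2")

    @property
    def random_region(self) -> tuple[int, int]:
        start = len(FLANK5_NT) // 3 + 1
        return start, start + self.region_len_aa - 1


def generate_random_orfs(config: SimulationConfig, rng=None) -> list[PeptideRecord]:
    """Draw a library of stop-free random-region ORFs at the target GC.

    Nucleotides are i.i.d. per position with P(G) = P(C) = gc_target / 2;
    any codon that lands on a stop is redrawn. Identical seeds give
    identical libraries.
    """
    if config.gc_target in (0.0, 1.0):
        # all-AT cannot avoid stop codons; all-GC is degenerate but legal
        if config.gc_target == 0.0:
            raise ValueError("gc_target = 0 cannot produce stop-free codons")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    g = config.gc_target / 2.0
    probs = [(1 - config.gc_target) / 2, g, g, (1 - config.gc_target) / 2]
    bases = np.array(list("ATGC"))
    records = []
    for i in range(config.n_lineages):
        codons = []
        for _ in range(config.region_len_aa):
            while True:
                codon = "".join(rng.choice(bases, size=3, p=probs))
                if codon not in STOP_CODONS:
                    codons.append(codon)
                    break
        nt = FLANK5_NT + "".join(codons) + FLANK3_NT
        aa = str(Seq(nt).translate())
        records.append(
            PeptideRecord(
                id=f"pep{i:05d}", aa_seq=aa, nt_variants=[nt],
                random_region=config.random_region,
            )
        )
    logger.info("generated %d random ORFs (region %d aa, GC target %.2f)",
                len(records), config.region_len_aa, config.gc_target)
    return records


def assign_true_fitness(
    records: list[PeptideRecord], config: SimulationConfig, rng=None
) -> dict[str, float]:
    """Composition-linear true fitness with Gaussian noise, truncated at 0.01.

    omega_true = 1 + sum_a true_effects[a] * freq_a + Normal(0, noise_sd).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    eff = np.array([config.true_effects.get(a, 0.0) for a in AMINO_ACIDS])
    out = {}
    for rec in records:
        f = aa_composition(rec).freq_vector()
        omega = 1.0 + float(f @ eff)
        if config.noise_sd > 0:
            omega += rng.normal(0.0, config.noise_sd)
        out[rec.id] = max(omega, 0.01)
    return out


def simulate_experiment(
    records: list[PeptideRecord],
    omega_true: dict[str, float],
    config: SimulationConfig,
    rng=None,
) -> tuple[Experiment, np.ndarray]:
    """Growth-dilution dynamics plus read sampling; returns (Experiment, W_true).

    Tracked lineages start at equal frequencies sharing 1 - empty_fraction0;
    the untagged empty-vector pool is a single mega-lineage at
    ``empty_fitness`` that raises or dilutes population mean fitness but
    yields no reads. Frequencies update deterministically as
    p <- p * omega / W with W the current mean fitness; reads at each
    timepoint are Poisson(N_t * p) for kappa = 1 or Polya negative
    binomial with mean N_t * p and variance kappa * N_t * p for kappa > 1.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = len(records)
    omega = np.array([omega_true[r.id] for r in records])
    p = np.full(n, (1.0 - config.empty_fraction0) / n)
    p_empty = config.empty_fraction0

    counts = np.zeros((n, config.T, config.n_replicates), dtype=np.int64)
    W_true = np.empty(config.T)
    for t in range(config.T):
        W = float(p @ omega + p_empty * config.empty_fitness)
        W_true[t] = W
        p = p * omega / W
        p_empty = p_empty * config.empty_fitness / W
        lam = config.depth * p
        if np.all(lam < 1e-12):
            raise RuntimeError(
                "tracked lineage frequencies collapsed to zero; increase depth "
                "or shorten the experiment"
            )
        for r in range(config.n_replicates):
            if config.kappa == 1.0:
                counts[:, t, r] = rng.poisson(lam)
            else:
                size = lam / (config.kappa - 1.0)
                counts[:, t, r] = rng.negative_binomial(size, 1.0 / config.kappa)
    totals = np.full((config.T, config.n_replicates), config.depth, dtype=np.int64)
    experiment = Experiment([r.id for r in records], counts, totals)
    return experiment, W_true


def spike_near_duplicates(
    records: list[PeptideRecord], config: SimulationConfig, rng=None
) -> tuple[list[PeptideRecord], list[set[str]]]:
    """Plant clusters of 2-5 mutants at Hamming distance 1-2 from parents.

    Mutations are applied at the codon level inside the random region so
    nucleotide and amino-acid sequences stay consistent. Returns the
    augmented record list and the true partition (one id-set per planted
    cluster; unlisted records are singletons).
    """
    if config.n_duplicate_clusters > len(records):
        raise ValueError("more duplicate clusters requested than records")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if config.n_duplicate_clusters == 0:
        return list(records), []
    g = config.gc_target / 2.0
    probs = [(1 - config.gc_target) / 2, g, g, (1 - config.gc_target) / 2]
    bases = np.array(list("ATGC"))
    out = list(records)
    truth = []
    parents = rng.choice(len(records), size=config.n_duplicate_clusters, replace=False)
    lo, hi = config.random_region
    for pi in parents:
        parent = records[int(pi)]
        cluster = {parent.id}
        for m in range(int(rng.integers(2, 6))):
            nt = list(parent.nt_variants[0])
            aa = list(parent.aa_seq)
            n_subs = int(rng.integers(1, 3))
            positions = rng.choice(np.arange(lo - 1, hi), size=n_subs, replace=False)
            for pos in positions:  # 0-based aa position within the whole peptide
                while True:
                    codon = "".join(rng.choice(bases, size=3, p=probs))
                    new_aa = str(Seq(codon).translate())
                    if codon not in STOP_CODONS and new_aa != aa[pos]:
                        break
                nt[3 * pos : 3 * pos + 3] = codon
                aa[pos] = new_aa
            mutant = PeptideRecord(
                id=f"{parent.id}m{m}", aa_seq="".join(aa),
                nt_variants=["".join(nt)], random_region=parent.random_region,
            )
            out.append(mutant)
            cluster.add(mutant.id)
        truth.append(cluster)
    logger.info("planted %d near-duplicate clusters (%d mutants)",
                len(truth), len(out) - len(records))
    return out, truth


def simulate(config: SimulationConfig):
    """One-call convenience: library + truth + counts.

    Returns a dict with records, omega_true, experiment, W_true and the
    planted-cluster truth partition.
    """
    rng = np.random.default_rng(config.seed)
    records = generate_random_orfs(config, rng)
    records, truth = spike_near_duplicates(records, config, rng)
    omega_true = assign_true_fitness(records, config, rng)
    experiment, W_true = simulate_experiment(records, omega_true, config, rng)
    return {
        "records": records,
        "omega_true": omega_true,
        "experiment": experiment,
        "W_true": W_true,
        "planted_clusters": truth,
    }
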