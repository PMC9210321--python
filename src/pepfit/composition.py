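"""Per-peptide composition predictors.

Everything here works at the level of the randomized region: amino-acid
counts and frequencies, GC content averaged over the nucleotide variants
that encode a peptide, and property-scale averages (volume, disorder
propensity, ...). Genetic-code facts (codon-position GC/AT constraint
classes, codon-number expected frequencies) are enumerated from the
standard table via Biopython.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .types import (
    AMINO_ACIDS,
    CodonConstraintClasses,
    CompositionRecord,
    PeptideRecord,
    PropertyScale,
)

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> residue over the 61 sense codons of the standard genetic code
SENSE_CODONS: dict[str, str] = dict(_STANDARD.forward_table)


def aa_composition(record: PeptideRecord) -> CompositionRecord:
    """Count residues over the random region; frequencies sum to 1."""
    region = record.region_aa
    bad = set(region) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"non-canonical residues {sorted(bad)} in random region of {record.id}"
        )
    counts = {a: region.count(a) for a in AMINO_ACIDS if a in region}
    return CompositionRecord(
        id=record.id,
        aa_counts=counts,
        region_length=len(region),
        gc=gc_content(record),
    )


def gc_content(record: PeptideRecord) -> float:
    """Unweighted mean GC fraction of the random region across nt variants."""
    fracs = []
    for variant in record.nt_variants:
        region = record.region_nt(variant)
        fracs.append((region.count("G") + region.count("C")) / len(region))
    return float(np.mean(fracs))


def scale_average(comp: CompositionRecord, scale: PropertyScale) -> float:
    """Frequency-weighted mean scale value, i.e. the mean over region residues."""
    missing = [a for a in comp.aa_counts if a not in scale.values]
    if missing:
        raise ValueError(
            f"scale {scale.name!r} missing residues {missing} present in {comp.id}"
        )
    return sum(
        c * scale.values[a] for a, c in comp.aa_counts.items()
    ) / comp.region_length


def annotate_scale_means(
    comps: list[CompositionRecord], scales: list[PropertyScale]
) -> None:
    """Fill ``scale_means`` on each composition record in place."""
    for comp in comps:
        for scale in scales:
            comp.scale_means[scale.name] = scale_average(comp, scale)


def codon_constraint_classes(position: int) -> CodonConstraintClasses:
    """Partition residues by their nucleotide constraint at a codon position.

    A residue is ``always_gc`` if every sense codon encoding it carries G
    or C at that position, ``always_at`` if every codon carries A or T,
    and ``mixed`` otherwise.
    """
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    by_aa: dict[str, list[str]] = {}
    for codon, aa in SENSE_CODONS.items():
        by_aa.setdefault(aa, []).append(codon[position - 1])
    always_gc, always_at, mixed = set(), set(), set()
    for aa, bases in by_aa.items():
        if all(b in "GC" for b in bases):
            always_gc.add(aa)
        elif all(b in "AT" for b in bases):
            always_at.add(aa)
        else:
            mixed.add(aa)
    return CodonConstraintClasses(
        position=position,
        always_gc=frozenset(always_gc),
        always_at=frozenset(always_at),
        mixed=frozenset(mixed),
    )


def expected_freq_from_codons() -> dict[str, float]:
    """Residue frequency expected from codon number alone (e.g. Ile -> 3/61)."""
    n_codons = {a: 0 for a in AMINO_ACIDS}
    for aa in SENSE_CODONS.values():
        n_codons[aa] += 1
    total = sum(n_codons.values())  # 61 sense codons
    return {a: c / total for a, c in n_codons.items()}


def ingest_external_scores(
    path, peptide_ids: list[str], sqrt_transform: bool = False
) -> dict[str, float]:
    """Join a TSV of precomputed per-peptide scores (id, score) onto peptides.

    Scores from external sequence predictors (disorder, solubility,
    aggregation, ...) are ingested as-is; an optional square-root
    transform is applied when configured. Unmatched ids are logged and
    excluded, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: expected columns id, score")
    scores = {}
    known = set(peptide_ids)
    for _, row in df.iterrows():
        try:
            val = float(row["score"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric score {row['score']!r} for id {row['id']}"
            ) from None
        if row["id"] not in known:
            logger.info("external score for unknown peptide %r excluded", row["id"])
            continue
        scores[row["id"]] = np.sqrt(val) if sqrt_transform else val
    logger.info(
        "ingested %d external scores (%d rows in file)", len(scores), len(df)
    )
    return scores
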