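"""Readers and writers for the tabular and sequence formats the pipeline touches.

Counts are exchanged as long-format TSV (id, timepoint, replicate, count)
with a totals sidecar keyed by (timepoint, replicate); sequences as FASTA
(Biopython); property scales as two-column CSV. Readers are strict: they
never silently drop rows, and every filter decision is logged at INFO.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AMINO_ACIDS, Experiment, PeptideRecord, PropertyScale

logger = logging.getLogger(__name__)

BUNDLED_SCALES = (
    "volume",
    "disorder_propensity",
    "synthesis_cost",
    "stickiness",
    "rsa",
    "isoelectric_point",
)


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


def read_counts_table(counts_path, totals_path) -> Experiment:
    """Read a long-format counts TSV plus a totals TSV into an Experiment.

    Absent (id, timepoint, replicate) cells are filled with 0. Duplicate
    cells and negative or non-integer counts are errors naming the row.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype={"id": str})
    _require_columns(df, ["id", "timepoint", "replicate", "count"], counts_path)
    for row_idx, val in df["count"].items():
        if pd.isna(val) or float(val) != int(val) or int(val) < 0:
            raise ParseError(
                f"{counts_path}: row {row_idx + 2} has invalid count {val!r} "
                "(must be a non-negative integer)"
            )
    dup = df.duplicated(subset=["id", "timepoint", "replicate"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ParseError(
            f"{counts_path}: duplicate cell (id={first['id']}, "
            f"timepoint={first['timepoint']}, replicate={first['replicate']})"
        )

    tot = pd.read_csv(totals_path, sep="\t")
    _require_columns(tot, ["timepoint", "replicate", "total"], totals_path)
    if tot.duplicated(subset=["timepoint", "replicate"]).any():
        raise ParseError(f"{totals_path}: duplicate (timepoint, replicate) row")

    timepoints = sorted(tot["timepoint"].unique())
    replicates = sorted(tot["replicate"].unique())
    if timepoints != list(range(1, len(timepoints) + 1)):
        raise ParseError(
            f"{totals_path}: timepoints must be 1..T, got {timepoints}"
        )
    t_index = {t: i for i, t in enumerate(timepoints)}
    r_index = {r: i for i, r in enumerate(replicates)}

    ids = list(dict.fromkeys(df["id"]))  # file order, deduplicated
    i_index = {pid: i for i, pid in enumerate(ids)}
    counts = np.zeros((len(ids), len(timepoints), len(replicates)), dtype=np.int64)
    for _, row in df.iterrows():
        t, r = row["timepoint"], row["replicate"]
        if t not in t_index or r not in r_index:
            raise ParseError(
                f"{counts_path}: (timepoint={t}, replicate={r}) not present "
                "in the totals table"
            )
        counts[i_index[row["id"]], t_index[t], r_index[r]] = int(row["count"])

    totals = np.zeros((len(timepoints), len(replicates)), dtype=np.int64)
    for _, row in tot.iterrows():
        totals[t_index[row["timepoint"]], r_index[row["replicate"]]] = int(row["total"])

    logger.info(
        "read %d count rows for %d peptides, %d timepoints, %d replicates from %s",
        len(df), len(ids), len(timepoints), len(replicates), counts_path,
    )
    return Experiment(ids, counts, totals)


def write_counts_table(experiment: Experiment, counts_path, totals_path) -> None:
    """Write an Experiment densely (every cell, zeros included)."""
    rows = []
    for i, pid in enumerate(experiment.peptide_ids):
        for t in range(experiment.n_timepoints):
            for r in range(experiment.n_replicates):
                rows.append((pid, t + 1, r + 1, int(experiment.counts[i, t, r])))
    pd.DataFrame(rows, columns=["id", "timepoint", "replicate", "count"]).to_csv(
        counts_path, sep="\t", index=False
    )
    tot_rows = [
        (t + 1, r + 1, int(experiment.totals[t, r]))
        for t in range(experiment.n_timepoints)
        for r in range(experiment.n_replicates)
    ]
    pd.DataFrame(tot_rows, columns=["timepoint", "replicate", "total"]).to_csv(
        totals_path, sep="\t", index=False
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs in file order."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    logger.info("read %d FASTA records from %s", len(out), path)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def build_peptide_records(
    aa_records: Sequence[tuple[str, str]],
    nt_records: Sequence[tuple[str, str]],
    random_region: tuple[int, int],
) -> list[PeptideRecord]:
    """Join amino-acid and nucleotide FASTAs by id into PeptideRecords.

    Nucleotide variant ids are either the peptide id itself or
    ``"<peptide id>|<variant tag>"``. Each variant must translate to the
    amino-acid sequence (standard code) with no internal stop codons.
    """
    variants: dict[str, list[str]] = {}
    for rid, seq in nt_records:
        pid = rid.split("|", 1)[0]
        variants.setdefault(pid, []).append(seq)

    out = []
    for pid, aa_seq in aa_records:
        nts = variants.get(pid)
        if not nts:
            raise ParseError(f"no nucleotide variant found for peptide {pid!r}")
        for nt in nts:
            n_codons = len(nt) // 3
            translated = str(Seq(nt[: 3 * n_codons]).translate())
            if "*" in translated.rstrip("*"):
                raise ParseError(f"internal stop codon in a variant of {pid!r}")
            covered = min(n_codons, len(aa_seq))
            if translated[:covered] != aa_seq[:covered]:
                raise ParseError(
                    f"nucleotide variant of {pid!r} does not translate to its "
                    "amino-acid sequence"
                )
        out.append(PeptideRecord(pid, aa_seq, nts, random_region))
    return out


def read_property_scale(path, name: Optional[str] = None) -> PropertyScale:
    """Read a residue,value CSV with exactly the 20 canonical residues."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["residue", "value"], path)
    values: dict[str, float] = {}
    for row_idx, row in df.iterrows():
        res = str(row["residue"]).strip().upper()
        try:
            val = float(row["value"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric value {row['value']!r} for residue {res}"
            ) from None
        if res in values:
            raise ParseError(f"{path}: duplicate residue {res}")
        values[res] = val
    # PropertyScale itself reports missing/unknown residues
    return PropertyScale(name or Path(str(path)).stem, values)


def bundled_scale(name: str) -> PropertyScale:
    """Load one of the property scales shipped with the package."""
    if name not in BUNDLED_SCALES:
        raise KeyError(f"unknown bundled scale {name!r}; have {BUNDLED_SCALES}")
    ref = importlib.resources.files("pepfit") / "data" / "scales" / f"{name}.csv"
    with importlib.resources.as_file(ref) as path:
        return read_property_scale(path, name=name)


def load_config(path) -> dict:
    """Load a flat key-value YAML config; CLI flags override these values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_fitness_table(fits, path, clusters: Optional[dict[str, int]] = None) -> None:
    """Write per-lineage fits as TSV (id, p0, omega, se, weight, classification, ...)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "id": f.id,
                "p0": f.p0,
                "omega": f.omega,
                "se": f.se,
                "weight": f.weight,
                "loglik": f.loglik,
                "classification": f.classification,
                "cluster": clusters.get(f.id, -1) if clusters else -1,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fitness_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    _require_columns(df, ["id", "omega", "se", "weight"], path)
    return df


def write_cluster_table(clusters, path) -> None:
    rows = []
    for ci, cl in enumerate(clusters):
        for member in cl.members:
            rows.append(
                {
                    "cluster_id": ci,
                    "member_id": member,
                    "is_representative": member == cl.representative,
                    "pseudo_fitness": cl.pseudo_fitness,
                    "pseudo_weight": cl.pseudo_weight,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trajectory_json(trajectory, dispersion, total_loglik, sweeps, converged, path):
    payload = {
        "W": [float(w) for w in trajectory.W],
        "kappa": float(dispersion.kappa),
        "kappa_at_boundary": bool(dispersion.at_boundary),
        "total_loglik": float(total_loglik),
        "sweeps": int(sweeps),
        "converged": bool(converged),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
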