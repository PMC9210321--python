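"""Single-link Hamming clustering of near-duplicate peptides.

Sequences a few substitutions apart are pseudoreplicates, not independent
draws from sequence space, so they are grouped by the transitive closure
of "Hamming distance <= cutoff" (union-find) and each cluster is collapsed
to a single weighted pseudo-datapoint. Distances are computed on the full
amino-acid sequence, non-random flanks included.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .types import Cluster, FitnessFit

logger = logging.getLogger(__name__)


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences must have equal length (got {len(a)} and {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def single_link_clusters(
    peptides: Sequence[tuple[str, str]], cutoff: int
) -> list[Cluster]:
    """Partition peptides into single-link clusters at a Hamming cutoff.

    ``peptides`` is a sequence of (id, amino-acid sequence) pairs, all of
    equal length. Two peptides share a cluster iff they are connected by a
    chain of pairwise distances <= cutoff. Output is deterministic:
    clusters sorted by their smallest member id, members sorted within.
    The placeholder representative (smallest id) is refined by
    :func:`collapse_clusters` once weights are known.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if not peptides:
        return []
    ids = [p[0] for p in peptides]
    seqs = [p[1] for p in peptides]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")

    # byte matrix lets numpy count mismatches for each row pair
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    uf = _UnionFind(len(seqs))
    for i in range(len(seqs)):
        d = (mat[i + 1 :] != mat[i]).sum(axis=1)
        for off in np.nonzero(d <= cutoff)[0]:
            uf.union(i, i + 1 + int(off))

    groups: dict[int, list[str]] = {}
    for i, pid in enumerate(ids):
        groups.setdefault(uf.find(i), []).append(pid)
    clusters = [
        Cluster(members=sorted(m), representative=min(m)) for m in groups.values()
    ]
    clusters.sort(key=lambda c: c.members[0])
    logger.info(
        "single-link clustering: %d peptides -> %d clusters at cutoff %d",
        len(ids), len(clusters), cutoff,
    )
    return clusters


def collapse_clusters(
    clusters: Sequence[Cluster],
    fitness_fits: dict[str, FitnessFit],
    mode: str = "weighted_mean",
) -> list[Cluster]:
    """Collapse each cluster to a pseudo-datapoint; set its representative.

    ``weighted_mean`` gives (sum w*f / sum w, sum w); ``representative``
    gives the (fitness, weight) of the highest-weight member. In both
    modes the representative is the max-weight member (ties broken by
    smallest id). Clusters whose members all have zero weight are dropped
    with a log entry.
    """
    if mode not in ("weighted_mean", "representative"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for cl in clusters:
        fits = [fitness_fits[m] for m in cl.members]
        weights = np.array([f.weight for f in fits])
        if weights.sum() == 0:
            logger.info("dropping cluster %s: all member weights are zero", cl.members)
            continue
        best = min(zip(cl.members, fits), key=lambda mf: (-mf[1].weight, mf[0]))
        if mode == "weighted_mean":
            f_vals = np.array([f.omega for f in fits])
            pseudo_f = float(np.sum(weights * f_vals) / weights.sum())
            pseudo_w = float(weights.sum())
        else:
            pseudo_f, pseudo_w = best[1].omega, best[1].weight
        out.append(
            Cluster(
                members=list(cl.members),
                representative=best[0],
                pseudo_fitness=pseudo_f,
                pseudo_weight=pseudo_w,
            )
        )
    return out
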