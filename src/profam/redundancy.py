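"""Greedy incremental sequence clustering at a fractional-identity threshold.

This reproduces the classic redundancy-removal strategy used to prepare
machine-learning datasets from public databases: sort by length, walk the
list once, and let each sequence either join the first cluster whose
representative it matches at >= threshold or found a new cluster. Only
representative-vs-candidate comparisons are made, so representatives end up
pairwise below the threshold.

Identity between two sequences is defined as the number of identical aligned
residue pairs in a global alignment maximising matches (match=+1, mismatch=0,
gap=0), divided by the length of the shorter sequence. A composition-based
prefilter skips pairs that provably cannot reach the threshold: the match
count never exceeds the per-residue count overlap sum(min(count_a, count_b)),
so the bound is exact and skipping never changes the clustering, only its
speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .seqio import CANONICAL_AA, ProteinRecord

DEFAULT_THRESHOLD = 0.90


@dataclass(frozen=True)
class Cluster:
    """One redundancy cluster: the representative plus all members.

    The representative is the longest member (first encountered on ties);
    every member matches it at >= the clustering threshold.
    """

    representative: ProteinRecord
    members: tuple[ProteinRecord, ...]
    identities: tuple[float, ...]  # member-vs-representative, aligned with members


def _match_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _match_aligner()


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Fractional identity between two sequences in [0, 1].

    Maximum number of identical aligned pairs over a global alignment
    (match=+1, everything else 0), divided by the shorter sequence length.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    matches = _ALIGNER.score(sa, sb)
    return matches / min(len(sa), len(sb))


def _residue_counts(seq: str) -> np.ndarray:
    return np.fromiter((seq.count(aa) for aa in CANONICAL_AA), dtype=np.int64, count=20)


def cluster(
    records: list[ProteinRecord],
    threshold: float = DEFAULT_THRESHOLD,
    prefilter: bool = True,
) -> list[Cluster]:
    """Greedy incremental clustering of ``records`` at ``threshold`` identity.

    Records are processed longest-first (stable for ties); each joins the
    first existing cluster whose *representative* it matches at >= threshold,
    otherwise it founds a new cluster. Deterministic for a fixed input order.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: -len(r.sequence))

    reps: list[ProteinRecord] = []
    rep_counts: list[np.ndarray] = []
    memberships: list[list[tuple[ProteinRecord, float]]] = []

    for rec in ordered:
        counts = _residue_counts(rec.sequence)
        if prefilter and reps:
            # upper bound on identity vs every representative; records are
            # processed longest-first so rec is never longer than a rep
            overlap = np.minimum(np.vstack(rep_counts), counts).sum(axis=1)
            feasible = overlap / len(rec.sequence) >= threshold
        else:
            feasible = np.ones(len(reps), dtype=bool)
        placed = False
        for ci, rep in enumerate(reps):
            if not feasible[ci]:
                continue
            ident = pairwise_identity(rec, rep)
            if ident >= threshold:
                memberships[ci].append((rec, ident))
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_counts.append(counts)
            memberships.append([(rec, 1.0)])

    return [
        Cluster(
            representative=rep,
            members=tuple(m for m, _ in mem),
            identities=tuple(i for _, i in mem),
        )
        for rep, mem in zip(reps, memberships)
    ]


def nonredundant(
    records: list[ProteinRecord],
    threshold: float = DEFAULT_THRESHOLD,
    prefilter: bool = True,
) -> list[ProteinRecord]:
    """Cluster representatives, in cluster-creation order."""
    return [c.representative for c in cluster(records, threshold, prefilter=prefilter)]


def membership_table(clusters: list[Cluster]) -> list[tuple[str, str, float]]:
    """Flatten clusters to (member_id, representative_id, identity) rows."""
    rows = []
    for c in clusters:
        for member, ident in zip(c.members, c.identities):
            rows.append((member.id, c.representative.id, ident))
    return rows
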