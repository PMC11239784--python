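"""Greedy centroid clustering of protein sequences at an identity threshold.

Reimplements the UCLUST-style redundancy-reduction step: sequences are
processed longest-first, each joining the first existing centroid it matches
at or above the identity threshold, otherwise founding a new cluster.
Identity is computed from an optimal global alignment (BLOSUM62, affine
gaps) with the shorter ungapped sequence as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import AA20, SequenceRecord

_AA_SET = frozenset(AA20)


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped strings + score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("gap-gap column in pairwise alignment")


@dataclass
class ClusterSet:
    """Result of greedy clustering: centroid ids and member -> centroid map."""

    threshold: float
    centroids: list[str]
    membership: dict[str, str]
    identities: dict[str, float] = field(default_factory=dict)

    def members_of(self, centroid: str) -> list[str]:
        return [m for m, c in self.membership.items() if c == centroid]


@lru_cache(maxsize=8)
def _aligner(matrix: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment under BLOSUM62 + affine gaps.

    The first gap position in a run costs *open_gap*, each further position
    *extend_gap*.  Traceback is deterministic (first optimal path reported
    by the aligner).
    """
    sa, sb = a.ungapped(), b.ungapped()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix, open_gap, extend_gap)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ga, gb, float(aln.score))


def percent_identity(pair: PairwiseAlignment) -> float:
    """Identical-residue columns over the shorter ungapped length, in [0, 1].

    'X' never counts as identical, even to another 'X'.
    """
    ident = sum(
        1
        for ca, cb in zip(pair.aligned_a, pair.aligned_b)
        if ca == cb and ca in _AA_SET
    )
    la = len(pair.aligned_a.replace("-", ""))
    lb = len(pair.aligned_b.replace("-", ""))
    return min(1.0, ident / min(la, lb))


def identity(a: SequenceRecord, b: SequenceRecord, **kwargs) -> float:
    """Convenience: global_align then percent_identity."""
    return percent_identity(global_align(a, b, **kwargs))


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float,
    best_match: bool = False,
    identity_fn: Callable[[SequenceRecord, SequenceRecord], float] | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at an identity *threshold*.

    Records are processed in order of decreasing ungapped length (ties broken
    lexicographically by id).  The first record founds a cluster; each
    subsequent record joins the first centroid (in creation order) whose
    identity to it is >= threshold, or the best-matching centroid when
    *best_match* is set, else founds a new cluster.  Deterministic: no
    randomness is involved.
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not 0.0 < threshold <= 1.0 or threshold != threshold:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ident = identity_fn or identity
    ordered = sorted(records, key=lambda r: (-len(r.ungapped()), r.id))
    by_id = {r.id: r for r in ordered}
    if len(by_id) != len(ordered):
        raise ValueError("duplicate sequence ids in clustering input")
    centroids: list[str] = []
    membership: dict[str, str] = {}
    identities: dict[str, float] = {}
    for rec in ordered:
        assigned = None
        best = -1.0
        for cid in centroids:
            pid = ident(rec, by_id[cid])
            if pid >= threshold:
                if not best_match:
                    assigned, best = cid, pid
                    break
                if pid > best:
                    assigned, best = cid, pid
        if assigned is None:
            centroids.append(rec.id)
            membership[rec.id] = rec.id
            identities[rec.id] = 1.0
        else:
            membership[rec.id] = assigned
            identities[rec.id] = best
    return ClusterSet(threshold, centroids, membership, identities)


def verify_cluster_invariants(
    clusters: ClusterSet, records: Sequence[SequenceRecord]
) -> None:
    """Recompute all member<->centroid and centroid<->centroid identities and
    assert the ClusterSet contract; raises AssertionError on violation."""
    by_id = {r.id: r for r in records}
    for cid in clusters.centroids:
        assert clusters.membership[cid] == cid, f"centroid {cid} not self-mapped"
    for member, cid in clusters.membership.items():
        if member == cid:
            continue
        pid = identity(by_id[member], by_id[cid])
        assert pid >= clusters.threshold, (
            f"member {member} identity {pid:.3f} to centroid {cid} "
            f"below threshold {clusters.threshold}"
        )
    for i, ci in enumerate(clusters.centroids):
        for cj in clusters.centroids[i + 1 :]:
            pid = identity(by_id[ci], by_id[cj])
            assert pid < clusters.threshold, (
                f"centroids {ci}/{cj} identity {pid:.3f} >= threshold"
            )
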