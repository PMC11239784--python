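"""Position-specific log-odds profiles for subfamily assignment.

Each subfamily is summarized by a PSSM over the anchored 52(+aux)-position
CSR block: score(p, a) = log2(f'_{p,a} / q_a) with pseudocounted
frequencies f'_{p,a} = (n_{p,a} + beta * q_a) / (N_p + beta) against a
background distribution q.  Because the block is produced by anchoring, the
indel-alignment problem a profile HMM solves does not arise here; the PSSM
carries the same per-position constraint information.

A query row is scored against every profile; it is assigned to the
best-scoring subfamily only when the margin over the runner-up reaches a
configurable number of bits and the best score is positive, else it is
reported "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .csr import CsrMatrix, PositionFrequencyTable, PositionKey
from .sequence_io import AA20

UNASSIGNED = "unassigned"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass
class ScoringProfile:
    """Per-position log-odds (bits) over the 20 residues, plus a gap penalty."""

    label: str
    positions: list[PositionKey]
    scores: np.ndarray  # (n_positions, 20), bits
    background: np.ndarray  # (20,), strictly positive, sums to 1
    beta: float
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.positions), 20):
            raise ValueError("scores must be (n_positions, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite (beta > 0 guarantees this)")


@dataclass
class SubfamilyCall:
    """Scores of one query against all profiles and the margin-based decision."""

    query_id: str
    scores: dict[str, float]
    best: str
    margin: float
    decision: str


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def build_profile(
    pft: PositionFrequencyTable,
    background: np.ndarray | None = None,
    beta: float = 1.0,
    gap_score: float = -2.0,
    label: str = "",
) -> ScoringProfile:
    """Estimate a log-odds profile from gap-excluded position counts.

    All-gap positions get all-zero (neutral) scores.
    """
    if beta <= 0:
        raise ValueError("pseudocount mass beta must be > 0")
    q = uniform_background() if background is None else np.asarray(background, float)
    if q.shape != (20,) or np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a strictly positive distribution over 20 residues")
    counts = pft.counts
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_prime = (counts + beta * q) / (totals + beta)
        scores = np.where(totals > 0, np.log2(f_prime / q), 0.0)
    return ScoringProfile(label, list(pft.positions), scores, q, beta, gap_score)


def score_row(profile: ScoringProfile, row: str) -> float:
    """Sum of per-position scores for a CSR-block row; gap and 'X' positions
    add the profile's gap score."""
    if len(row) != len(profile.positions):
        raise ValueError(
            f"row width {len(row)} does not match profile width {len(profile.positions)}"
        )
    total = 0.0
    for p, ch in enumerate(row):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            total += profile.gap_score
        else:
            total += float(profile.scores[p, idx])
    return total


def classify(
    profiles: Sequence[ScoringProfile],
    row: str,
    query_id: str = "",
    delta: float = 5.0,
) -> SubfamilyCall:
    """Assign a row to the best-scoring profile when the margin and positivity
    rules are met; ties break lexicographically by label."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to classify")
    if delta < 0:
        raise ValueError("margin delta must be >= 0")
    scores = {p.label: score_row(p, row) for p in profiles}
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_label, best_score = ordered[0]
    margin = best_score - ordered[1][1]
    decision = best_label if (margin >= delta and best_score > 0) else UNASSIGNED
    return SubfamilyCall(query_id, scores, best_label, margin, decision)


def profiles_from_matrix(
    matrix: CsrMatrix,
    labels: dict[str, str],
    beta: float = 1.0,
    gap_score: float = -2.0,
    background: np.ndarray | None = None,
    exclude: str | None = None,
) -> list[ScoringProfile]:
    """Build one profile per label from a labelled CSR matrix; *exclude* drops
    one sequence (leave-one-out support)."""
    from .csr import position_frequencies

    by_label: dict[str, list[str]] = {}
    for sid in matrix.ids():
        if sid == exclude:
            continue
        by_label.setdefault(labels[sid], []).append(sid)
    out = []
    for label in sorted(by_label):
        pft = position_frequencies(matrix, by_label[label])
        out.append(build_profile(pft, background, beta, gap_score, label))
    return out
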