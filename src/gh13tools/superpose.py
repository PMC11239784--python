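"""Rigid-body C-alpha superposition over the canonical A+B+C domains.

Residue correspondence between two chains comes from a global sequence
alignment of the domain-restricted amino-acid strings (the compared
proteins are homologous); the optimal least-squares rigid transform is the
closed-form Kabsch solution (reflections excluded), and pairs beyond a
distance cutoff are pruned and the fit repeated until stable — yielding the
"corresponding C-alpha atoms" count and RMSD used to compare family
members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster import global_align
from .sequence_io import CoordinateSet, SequenceRecord


@dataclass
class ResidueCorrespondence:
    """Sequence-collinear index pairs into two CoordinateSet residue lists."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        last_a = last_b = -1
        for a, b in self.pairs:
            if a <= last_a or b <= last_b:
                raise ValueError("correspondence must be strictly increasing in both coordinates")
            last_a, last_b = a, b

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    n_input_pairs: int
    n_retained_pairs: int
    rmsd: float
    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)
    iterations: int
    cutoff: float
    retained: list[tuple[int, int]] | None = None


def _restrict(cs: CoordinateSet, ranges: Sequence[tuple[int, int]] | None) -> list[int]:
    if ranges is None:
        return list(range(len(cs.residues)))
    out = []
    for i, (num, _aa, _x, _y, _z) in enumerate(cs.residues):
        if any(lo <= num <= hi for lo, hi in ranges):
            out.append(i)
    return out


def pair_residues(
    a: CoordinateSet,
    b: CoordinateSet,
    domains_a: Sequence[tuple[int, int]] | None = None,
    domains_b: Sequence[tuple[int, int]] | None = None,
) -> ResidueCorrespondence:
    """Pair residues of two chains by globally aligning their
    domain-restricted sequences; aligned non-gap columns become pairs
    (indices refer to the full residue lists)."""
    ia = _restrict(a, domains_a)
    ib = _restrict(b, domains_b)
    if not ia or not ib:
        raise ValueError("empty domain restriction")
    seq_a = "".join(a.residues[i][1] for i in ia)
    seq_b = "".join(b.residues[i][1] for i in ib)
    aln = global_align(
        SequenceRecord(a.label or "a", seq_a), SequenceRecord(b.label or "b", seq_b)
    )
    pairs: list[tuple[int, int]] = []
    pa = pb = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            pairs.append((ia[pa], ib[pb]))
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
    return ResidueCorrespondence(pairs)


def kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y.

    Returns (R, t, rmsd) with R a proper rotation (det +1) and
    Y ~ R @ X + t; rmsd is over all pairs after the transform.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - cx, Y - cy
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:
        raise ValueError("degenerate (collinear) geometry")
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    delta = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((delta**2).sum(axis=1).mean()))
    return R, t, rmsd


def iterative_prune_superpose(
    a: CoordinateSet,
    b: CoordinateSet,
    corr: ResidueCorrespondence,
    cutoff: float = 2.0,
    max_iterations: int = 100,
) -> SuperpositionResult:
    """Fit, drop pairs with post-fit distance > cutoff, refit; iterate until
    the pair set is stable or only three pairs remain."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    Xa = a.coords()
    Xb = b.coords()
    pairs = list(corr.pairs)
    if len(pairs) < 3:
        raise ValueError("need at least three corresponding pairs")
    iterations = 0
    while True:
        iterations += 1
        X = Xa[[p[0] for p in pairs]]
        Y = Xb[[p[1] for p in pairs]]
        R, t, rmsd = kabsch(X, Y)
        dists = np.sqrt((((X @ R.T + t) - Y) ** 2).sum(axis=1))
        keep = [p for p, d in zip(pairs, dists) if d <= cutoff]
        if len(keep) == len(pairs) or len(keep) <= 3 or iterations >= max_iterations:
            if len(keep) >= 3 and len(keep) != len(pairs):
                X = Xa[[p[0] for p in keep]]
                Y = Xb[[p[1] for p in keep]]
                R, t, rmsd = kabsch(X, Y)
                pairs = keep
            return SuperpositionResult(
                n_input_pairs=len(corr.pairs),
                n_retained_pairs=len(pairs),
                rmsd=rmsd,
                rotation=R,
                translation=t,
                iterations=iterations,
                cutoff=cutoff,
                retained=pairs,
            )
        pairs = keep
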