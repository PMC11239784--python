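"""The 52-position CSR coordinate system and its statistics.

Family GH13 carries seven conserved sequence regions (CSR-I..CSR-VII).  On
the logo coordinate system used here they tile positions 1..52, in
N-to-C-terminal order CSR-VI, CSR-I, CSR-V, CSR-II, CSR-III, CSR-IV,
CSR-VII, with the catalytic triad at fixed coordinates: the nucleophile Asp
at 25 (CSR-II), the proton donor Glu at 34 (CSR-III) and the
transition-state stabilizer Asp at 43 (CSR-IV).  An auxiliary anchored
position "preCSRV" (the residue immediately N-terminal to logo 16) carries
the Asp of the non-reducing-end carbohydrate-binding site in the maltogenic
amylase subfamily.

The scheme is projected onto a multiple alignment by anchoring each logo
position to the alignment column of the corresponding reference-sequence
residue; all conservation counts, position frequency tables, logo tables
and fingerprint checks then operate on the extracted 52(+aux)-column block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AA20, Alignment

PositionKey = int | str  # 1..52 or an auxiliary name such as "preCSRV"

DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "CSR-VI": (1, 9),
    "CSR-I": (10, 15),
    "CSR-V": (16, 20),
    "CSR-II": (21, 29),
    "CSR-III": (30, 37),
    "CSR-IV": (38, 43),
    "CSR-VII": (44, 52),
}

DEFAULT_CATALYTIC: dict[str, int] = {
    "nucleophile": 25,
    "acid_base": 34,
    "stabilizer": 43,
}

CATALYTIC_RESIDUES: dict[str, str] = {
    "nucleophile": "D",
    "acid_base": "E",
    "stabilizer": "D",
}


@dataclass(frozen=True)
class CsrScheme:
    """Logo coordinate system: region ranges, catalytic positions, auxiliaries."""

    regions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    catalytic: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CATALYTIC))
    auxiliary: tuple[str, ...] = ("preCSRV",)

    def __post_init__(self) -> None:
        covered: list[int] = []
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name} has inverted range {lo}-{hi}")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, 53)) or len(covered) != 52:
            raise ValueError("CSR regions must disjointly cover logo positions 1..52")
        for role, pos in self.catalytic.items():
            if not 1 <= pos <= 52:
                raise ValueError(f"catalytic position {role}={pos} outside 1..52")

    def region_of(self, position: int) -> str:
        for name, (lo, hi) in self.regions.items():
            if lo <= position <= hi:
                return name
        raise KeyError(position)

    @property
    def positions(self) -> list[PositionKey]:
        return list(range(1, 53)) + list(self.auxiliary)


@dataclass
class CsrColumnMap:
    """Projection of logo positions (and auxiliaries) onto 0-based alignment columns."""

    columns: dict[PositionKey, int]

    def __post_init__(self) -> None:
        core = [self.columns[p] for p in range(1, 53) if p in self.columns]
        if any(b <= a for a, b in zip(core, core[1:])):
            raise ValueError("mapped alignment columns must strictly increase in logo order")

    def __getitem__(self, key: PositionKey) -> int:
        return self.columns[key]

    def __contains__(self, key: PositionKey) -> bool:
        return key in self.columns

    @property
    def positions(self) -> list[PositionKey]:
        ints = sorted(k for k in self.columns if isinstance(k, int))
        auxs = sorted(k for k in self.columns if isinstance(k, str))
        return ints + auxs


@dataclass
class CsrMatrix:
    """Per-sequence characters at the mapped logo positions, in logo order
    (positions 1..52 first, auxiliary names appended)."""

    positions: list[PositionKey]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        width = len(self.positions)
        for sid, row in self.rows.items():
            if len(row) != width:
                raise ValueError(f"row {sid} has width {len(row)}, expected {width}")
        self._index = {p: i for i, p in enumerate(self.positions)}

    def char(self, seq_id: str, position: PositionKey) -> str:
        return self.rows[seq_id][self._index[position]]

    def ids(self) -> list[str]:
        return list(self.rows)


@dataclass
class ConservationStat:
    """Count of sequences matching a per-position allowed-set specification."""

    spec: dict[PositionKey, frozenset[str]]
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total


@dataclass
class Fingerprint:
    """A named set of (position, allowed residues, description) constraints."""

    label: str
    positions: list[tuple[PositionKey, frozenset[str], str]]

    def __post_init__(self) -> None:
        for pos, allowed, _ in self.positions:
            if not allowed:
                raise ValueError(f"fingerprint {self.label}: empty allowed set at {pos}")

    def as_spec(self) -> dict[PositionKey, frozenset[str]]:
        return {pos: allowed for pos, allowed, _ in self.positions}


@dataclass
class FingerprintReport:
    """Per-position match booleans for one sequence row."""

    label: str
    matches: dict[PositionKey, bool]

    @property
    def fraction(self) -> float:
        return sum(self.matches.values()) / len(self.matches)


class PositionFrequencyTable:
    """Gap-excluded residue frequencies per logo position.

    Counts are kept internally (they are what profile building needs); the
    spec-level view is frequencies summing to 1 per position plus a gap
    fraction.  'X' is excluded from the 20-state mass, like gaps.
    """

    def __init__(self, positions: list[PositionKey], counts: np.ndarray,
                 gap_counts: np.ndarray, n_sequences: int) -> None:
        if counts.shape != (len(positions), 20):
            raise ValueError("counts must be (n_positions, 20)")
        self.positions = positions
        self.counts = counts.astype(float)
        self.gap_counts = gap_counts.astype(float)
        self.n_sequences = n_sequences

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    @property
    def gap_fraction(self) -> np.ndarray:
        return self.gap_counts / self.n_sequences

    def consensus(self) -> str:
        """Most frequent residue per position ('-' where all-gap); ties break
        alphabetically."""
        freq = self.frequencies
        out = []
        for p in range(len(self.positions)):
            if self.counts[p].sum() == 0:
                out.append("-")
            else:
                out.append(AA20[int(np.argmax(freq[p]))])
        return "".join(out)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AA20))
        df.insert(0, "position", [str(p) for p in self.positions])
        df["gap_fraction"] = self.gap_fraction
        df["n_sequences"] = self.n_sequences
        return df


def anchor_csr_columns(
    alignment: Alignment,
    reference_id: str,
    reference_logo_residues: Mapping[int, int],
    scheme: CsrScheme | None = None,
    allow_aberrant: bool = False,
) -> CsrColumnMap:
    """Anchor the logo coordinate system onto alignment columns.

    *reference_logo_residues* maps logo positions (1..52) to 0-based ungapped
    residue indices of the reference sequence.  Each logo position is mapped
    to the alignment column holding that reference residue.  The reference
    residues at the catalytic positions must read D/E/D unless
    *allow_aberrant* is set (aberrant-triad members do occur in the family).
    Auxiliary positions of the scheme are anchored relative to the core: the
    default "preCSRV" is the column of the reference residue immediately
    N-terminal to logo position 16.
    """
    scheme = scheme or CsrScheme()
    ref = alignment.get(reference_id)
    ungapped_to_col: list[int] = [
        col for col, ch in enumerate(ref.residues) if ch != "-"
    ]
    n_res = len(ungapped_to_col)

    items = sorted(reference_logo_residues.items())
    if [k for k, _ in items] and not all(
        b > a for (_, a), (_, b) in zip(items, items[1:])
    ):
        raise ValueError("reference residue indices must strictly increase in logo order")
    columns: dict[PositionKey, int] = {}
    for logo_pos, res_idx in items:
        if not 0 <= res_idx < n_res:
            raise ValueError(
                f"reference residue index {res_idx} out of range (0..{n_res - 1})"
            )
        columns[logo_pos] = ungapped_to_col[res_idx]

    if not allow_aberrant:
        for role, pos in scheme.catalytic.items():
            if pos not in reference_logo_residues:
                continue
            res = ref.residues[columns[pos]]
            want = CATALYTIC_RESIDUES[role]
            if res != want:
                raise ValueError(
                    f"catalytic {role.replace('_', '/')} at logo position {pos} "
                    f"is not {want} in reference {reference_id} (found {res}); "
                    f"pass allow_aberrant=True to override"
                )

    for aux in scheme.auxiliary:
        if aux == "preCSRV" and 16 in reference_logo_residues:
            idx = reference_logo_residues[16] - 1
            if idx >= 0:
                columns[aux] = ungapped_to_col[idx]
    return CsrColumnMap(columns)


def extract_csr_block(alignment: Alignment, cmap: CsrColumnMap) -> CsrMatrix:
    """Pull the characters at the mapped columns, in logo order, per sequence."""
    positions = cmap.positions
    cols = [cmap[p] for p in positions]
    rows = {r.id: "".join(r.residues[c] for c in cols) for r in alignment.records}
    return CsrMatrix(positions, rows)


def conservation_count(
    matrix: CsrMatrix,
    spec: Mapping[PositionKey, Iterable[str]],
    subset: Sequence[str] | None = None,
) -> ConservationStat:
    """Sequences whose residues at ALL listed positions fall in the allowed
    sets; gaps and 'X' never match."""
    ids = list(subset) if subset is not None else matrix.ids()
    if not ids:
        raise ValueError("empty subset")
    norm = {pos: frozenset(allowed) for pos, allowed in spec.items()}
    for pos in norm:
        if pos not in matrix._index:
            raise KeyError(f"unknown position {pos!r}")
    count = 0
    for sid in ids:
        ok = True
        for pos, allowed in norm.items():
            ch = matrix.char(sid, pos)
            if ch in ("-", "X") or ch not in allowed:
                ok = False
                break
        count += ok
    return ConservationStat(dict(norm), count, len(ids))


def position_frequencies(
    matrix: CsrMatrix, subset: Sequence[str] | None = None
) -> PositionFrequencyTable:
    """Gap-excluded per-position residue counts/frequencies over *subset*."""
    ids = list(subset) if subset is not None else matrix.ids()
    if not ids:
        raise ValueError("empty subset")
    aa_index = {a: i for i, a in enumerate(AA20)}
    P = len(matrix.positions)
    counts = np.zeros((P, 20))
    gaps = np.zeros(P)
    for sid in ids:
        row = matrix.rows[sid]
        for p, ch in enumerate(row):
            if ch == "-":
                gaps[p] += 1
            elif ch in aa_index:
                counts[p, aa_index[ch]] += 1
    return PositionFrequencyTable(matrix.positions, counts, gaps, len(ids))


def make_logo_table(pft: PositionFrequencyTable) -> pd.DataFrame:
    """Information content (bits) and residue letter heights per position.

    IC_p = log2(20) - H_p with H_p the Shannon entropy of the gap-excluded
    frequencies; height(a, p) = f_{p,a} * IC_p.  All-gap positions carry
    IC 0 by convention.
    """
    freq = pft.frequencies
    rows = []
    for p, pos in enumerate(pft.positions):
        f = freq[p]
        if f.sum() == 0:
            ic = 0.0
        else:
            nz = f[f > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
            ic = math.log2(20) - entropy
        row = {"position": str(pos), "information_bits": ic}
        for a, fa in zip(AA20, f):
            row[a] = fa * ic
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_fingerprint(
    matrix: CsrMatrix, seq_id: str, fingerprint: Fingerprint
) -> FingerprintReport:
    """Check one sequence row against a fingerprint; gaps and 'X' fail."""
    matches: dict[PositionKey, bool] = {}
    for pos, allowed, _ in fingerprint.positions:
        ch = matrix.char(seq_id, pos)
        matches[pos] = ch not in ("-", "X") and ch in allowed
    return FingerprintReport(fingerprint.label, matches)
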