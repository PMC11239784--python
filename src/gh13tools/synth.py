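"""Seeded generators for labelled benchmark sequences and toy structures.

The sequence generator emulates the statistical structure the delineation
analysis assumes: each subfamily has a 52-position CSR block placed inside
a longer protein, with per-position consensus residue sets emitted at
stated conservation probabilities on a uniform random background, and the
catalytic triad D25/E34/D43 emitted deterministically (unless a spec marks
the aberrant-triad variant).  Classes are i.i.d. around their consensus —
there is no tree-structured substitution process.  The toy-structure
generator produces C-alpha coordinate pairs related by a known rigid
transform plus per-point noise of stated magnitude.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .csr import CsrColumnMap, CsrScheme, Fingerprint, PositionKey
from .sequence_io import AA20, Alignment, CoordinateSet, SequenceRecord


@dataclass
class PositionModel:
    """Allowed residue set (first member = consensus, weight 4 vs 1) emitted
    with probability *c*; otherwise a uniform non-member residue."""

    residues: str
    c: float

    def __post_init__(self) -> None:
        if not self.residues or not set(self.residues) <= set(AA20):
            raise ValueError(f"invalid residue set {self.residues!r}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"conservation probability {self.c} outside [0,1]")


@dataclass
class SubfamilySpec:
    """Generative model of one subfamily's sequences."""

    label: str
    length: int
    placement: dict[PositionKey, int]  # logo position / aux name -> ungapped index
    positions: dict[PositionKey, PositionModel]
    background: str = AA20
    indel_rate: float = 0.0
    aberrant_triad: bool = False

    def __post_init__(self) -> None:
        core = [self.placement[p] for p in sorted(
            (k for k in self.placement if isinstance(k, int)))]
        if any(b <= a for a, b in zip(core, core[1:])):
            raise ValueError("CSR placements must strictly increase in logo order")
        if core and (core[0] < 0 or core[-1] >= self.length):
            raise ValueError("CSR placement outside sequence length")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel rate must be in [0,1)")


@dataclass
class BenchmarkSet:
    """Labelled benchmark: records, truth map, and generation provenance."""

    records: list[SequenceRecord]
    truth: dict[str, str]
    seed: int
    parameters: dict
    alignment: Alignment | None = None
    column_map: CsrColumnMap | None = None
    refmap: dict[int, int] | None = None  # logo position -> ungapped ref index

    def __post_init__(self) -> None:
        for r in self.records:
            if r.id not in self.truth:
                raise ValueError(f"record {r.id} lacks a truth label")


def _sample_position(model: PositionModel, rng: np.random.Generator) -> str:
    if rng.random() < model.c:
        members = model.residues
        if len(members) == 1:
            return members
        weights = np.array([4.0] + [1.0] * (len(members) - 1))
        return members[rng.choice(len(members), p=weights / weights.sum())]
    others = [a for a in AA20 if a not in model.residues]
    return others[rng.integers(len(others))]


def sample_sequence(
    spec: SubfamilySpec, rng: np.random.Generator, seq_id: str = "seq"
) -> SequenceRecord:
    """Draw one sequence from a subfamily spec.

    Fingerprint/CSR positions follow their PositionModel; the catalytic
    triad is emitted as D/E/D with probability 1 unless the spec is marked
    aberrant (then the nucleophile position falls back to background);
    remaining positions are uniform background, with optional indels in the
    non-CSR segments.
    """
    chars = [spec.background[rng.integers(len(spec.background))] for _ in range(spec.length)]
    anchored = set(spec.placement.values())
    catalytic = {25: "D", 34: "E", 43: "D"}
    for pos_key, idx in spec.placement.items():
        if isinstance(pos_key, int) and pos_key in catalytic and not spec.aberrant_triad:
            chars[idx] = catalytic[pos_key]
        elif pos_key in spec.positions:
            chars[idx] = _sample_position(spec.positions[pos_key], rng)
    if spec.indel_rate > 0:
        out = []
        for i, ch in enumerate(chars):
            if i in anchored:
                out.append(ch)
                continue
            if rng.random() < spec.indel_rate:  # deletion
                continue
            out.append(ch)
            if rng.random() < spec.indel_rate:  # insertion
                out.append(spec.background[rng.integers(len(spec.background))])
        chars = out
    return SequenceRecord(seq_id, "".join(chars))


def make_benchmark(
    specs: Sequence[SubfamilySpec],
    n_per_class: Mapping[str, int],
    seed: int = 0,
) -> BenchmarkSet:
    """Generate n_per_class sequences per subfamily spec.

    When every spec has indel rate 0, the set is also emitted as a trivially
    aligned (gapless) Alignment with the ground-truth CsrColumnMap, usable
    as the anchoring oracle.
    """
    if len(specs) < 2:
        raise ValueError("need at least two subfamily specs")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for spec in specs:
        n = n_per_class[spec.label]
        for k in range(n):
            sid = f"{spec.label}_{k:04d}"
            rec = sample_sequence(spec, rng, sid)
            records.append(rec)
            truth[sid] = spec.label
    gapless = all(s.indel_rate == 0 for s in specs)
    alignment = column_map = refmap = None
    if gapless and len({s.length for s in specs}) == 1:
        alignment = Alignment(list(records))
        placement = specs[0].placement
        column_map = CsrColumnMap({k: v for k, v in placement.items()})
        refmap = {k: v for k, v in placement.items() if isinstance(k, int)}
    params = {
        "n_per_class": dict(n_per_class),
        "labels": [s.label for s in specs],
    }
    return BenchmarkSet(records, truth, seed, params, alignment, column_map, refmap)


@dataclass
class ToyStructureTruth:
    """Generating transform and analytic noise RMSD of a toy pair."""

    rotation: np.ndarray
    translation: np.ndarray
    noise_rmsd: float


def make_toy_structures(
    n_points: int, displacement: float, seed: int = 0
) -> tuple[CoordinateSet, CoordinateSet, ToyStructureTruth]:
    """A random C-alpha trace A and its copy B = R A + t + noise.

    *displacement* is the root-mean-square per-point displacement (A); the
    analytic RMSD of the realized noise is returned (the optimal
    superposition RMSD is bounded above by it).
    """
    if n_points < 4:
        raise ValueError("need at least four points")
    rng = np.random.default_rng(seed)
    A = rng.normal(scale=10.0, size=(n_points, 3))
    # random proper rotation via QR
    Q, Rq = np.linalg.qr(rng.normal(size=(3, 3)))
    Q = Q @ np.diag(np.sign(np.diag(Rq)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    noise = rng.normal(scale=displacement / np.sqrt(3.0), size=(n_points, 3)) \
        if displacement > 0 else np.zeros((n_points, 3))
    B = A @ Q.T + t + noise
    noise_rmsd = float(np.sqrt((noise**2).sum(axis=1).mean()))
    aas = [AA20[rng.integers(20)] for _ in range(n_points)]
    set_a = CoordinateSet("toyA", "A", [
        (i + 1, aas[i], *map(float, A[i])) for i in range(n_points)
    ])
    set_b = CoordinateSet("toyB", "A", [
        (i + 1, aas[i], *map(float, B[i])) for i in range(n_points)
    ])
    return set_a, set_b, ToyStructureTruth(Q, t, noise_rmsd)


# ---------------------------------------------------------------------------
# shipped benchmark configuration


def default_config_path() -> Path:
    return Path(importlib.resources.files("gh13tools") / "data" / "benchmark.yaml")


def load_benchmark_config(path: str | Path | None = None) -> dict:
    """Parse the benchmark YAML into specs, fingerprints and defaults."""
    path = Path(path) if path else default_config_path()
    raw = yaml.safe_load(path.read_text())
    scheme = CsrScheme()
    placement: dict[PositionKey, int] = {}
    for region, (lo, hi) in scheme.regions.items():
        start = raw["placement"][region]
        for offset, logo in enumerate(range(lo, hi + 1)):
            placement[logo] = start + offset
    placement["preCSRV"] = placement[16] - 1
    default_c = float(raw.get("default_conservation", 0.85))
    specs: dict[str, SubfamilySpec] = {}
    for label, cls in raw["classes"].items():
        consensus = cls["consensus"]
        if len(consensus) != 52:
            raise ValueError(f"class {label}: consensus must be 52 residues")
        positions: dict[PositionKey, PositionModel] = {}
        for logo in range(1, 53):
            if logo in (25, 34, 43):
                continue
            positions[logo] = PositionModel(consensus[logo - 1], default_c)
        for key, entry in (cls.get("positions") or {}).items():
            positions[int(key)] = PositionModel(str(entry["set"]), float(entry["c"]))
        for aux, entry in (cls.get("auxiliary") or {}).items():
            positions[aux] = PositionModel(str(entry["set"]), float(entry["c"]))
        specs[label] = SubfamilySpec(
            label=label,
            length=int(raw["length"]),
            placement=dict(placement),
            positions=positions,
            indel_rate=float(raw.get("indel_rate", 0.0)),
        )
    fingerprints: dict[str, list[Fingerprint]] = {}
    for group, entries in raw["fingerprints"].items():
        fps = []
        for entry in entries:
            pos_list = []
            for key, allowed in entry["positions"].items():
                pos_key: PositionKey = int(key) if str(key).isdigit() else str(key)
                pos_list.append((pos_key, frozenset(str(allowed)), entry.get("description", "")))
            fps.append(Fingerprint(entry["name"], pos_list))
        fingerprints[group] = fps
    return {
        "scheme": scheme,
        "specs": specs,
        "fingerprints": fingerprints,
        "n_per_class": {k: int(v) for k, v in raw["n_per_class"].items()},
        "placement": placement,
    }
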