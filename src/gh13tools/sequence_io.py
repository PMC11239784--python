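"""Reading and writing the standard formats of the delineation pipeline.

FASTA / aligned FASTA for sequences, PDB ATOM records for C-alpha
coordinates, Newick for trees and TSV for tabular reports.  Sequences are
kept as plain strings over the 20-letter amino-acid alphabet plus ``X``
(unknown) and ``-`` (gap, aligned context only); ambiguity codes (B, Z, U,
O, J) are mapped to ``X`` with a logged warning because every downstream
frequency table is 20-state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: canonical amino-acid alphabet used throughout the package
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}


class SequenceFormatError(ValueError):
    """Raised for malformed or inconsistent sequence input."""


@dataclass
class SequenceRecord:
    """A named amino-acid sequence, gapped or ungapped."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered multiple sequence alignment; all rows equal length."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceFormatError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            detail = ", ".join(f"{r.id}:{len(r)}" for r in self.records[:8])
            raise SequenceFormatError(f"ragged alignment (lengths {detail})")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence {seq_id!r} not in alignment")

    def slice_columns(self, start: int, stop: int) -> "Alignment":
        """Columns ``start..stop`` inclusive, 0-based, all rows."""
        return Alignment(
            [
                SequenceRecord(r.id, r.residues[start : stop + 1], r.description)
                for r in self.records
            ]
        )


@dataclass
class CoordinateSet:
    """Ordered C-alpha trace of one chain: (residue number, 1-letter aa, x, y, z)."""

    label: str
    chain: str
    residues: list[tuple[int, str, float, float, float]]

    @property
    def sequence(self) -> str:
        return "".join(r[1] for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([[r[2], r[3], r[4]] for r in self.residues], dtype=float)

    def numbers(self) -> list[int]:
        return [r[0] for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


def _clean(raw: str, seq_id: str, allow_gap: bool) -> str:
    out = []
    warned = False
    for ch in raw.upper():
        if ch.isspace():
            continue
        if ch == ".":
            ch = "-"
        if ch == "-":
            if not allow_gap:
                raise SequenceFormatError(
                    f"sequence {seq_id!r} contains gaps; use read_alignment for aligned input"
                )
            out.append(ch)
            continue
        if ch in _AMBIGUOUS:
            if not warned:
                logger.warning("sequence %s: mapping ambiguous letter(s) %s to X", seq_id, ch)
                warned = True
            ch = "X"
        if ch != "X" and ch not in _AA_SET:
            raise SequenceFormatError(f"sequence {seq_id!r}: invalid residue letter {ch!r}")
        out.append(ch)
    return "".join(out)


def _read_records(path: str | Path, allow_gap: bool) -> list[SequenceRecord]:
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        residues = _clean(str(rec.seq), rec.id, allow_gap)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise SequenceFormatError(f"no sequences found in {path}")
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped FASTA; order preserved, residues uppercased."""
    return _read_records(path, allow_gap=False)


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA; '.' gap dialect normalized to '-'."""
    return Alignment(_read_records(path, allow_gap=True))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def write_alignment(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    write_fasta(alignment.records, path, width=width)


def read_ca_coordinates(path: str | Path, chain: str, label: str | None = None) -> CoordinateSet:
    """Extract the C-alpha trace of one chain from a PDB file.

    First model only; HETATM ignored; for alternate locations the blank
    altloc is preferred, then 'A', else the first one seen.  Unknown residue
    names become 'X'.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or path.stem, str(path))
    model = next(iter(structure))
    chains = {c.id for c in model}
    if chain not in chains:
        raise SequenceFormatError(
            f"chain {chain!r} not in {path.name}; available: {sorted(chains)}"
        )
    residues: list[tuple[int, str, float, float, float]] = []
    for res in model[chain]:
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue
        if "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            alts = {a.get_altloc(): a for a in atom.disordered_get_list()}
            atom = alts.get(" ") or alts.get("A") or atom.disordered_get_list()[0]
        name = res.get_resname().capitalize()
        aa = protein_letters_3to1.get(name, "X")
        x, y, z = (float(v) for v in atom.coord)
        residues.append((int(resseq), aa, x, y, z))
    if not residues:
        raise SequenceFormatError(f"chain {chain!r} of {path.name} has no CA atoms")
    return CoordinateSet(label or path.stem, chain, residues)


def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialize a phylogeny.Tree as Newick with branch lengths and integer
    percent supports as internal node labels; optionally write to *path*."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path):
    """Parse Newick text (or a file path) into a phylogeny.Tree via dendropy."""
    from . import phylogeny

    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return phylogeny.Tree.from_newick(text)


def write_tsv(frame, path: str | Path) -> None:
    """Uniform TSV writer for tabular reports (pandas DataFrame)."""
    frame.to_csv(path, sep="\t", index=False)
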