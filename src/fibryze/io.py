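"""Structure and sequence input/output.

Covers the three formats the analysis consumes: legacy PDB v3.3
(``ATOM``/``HETATM``/``MODEL``/``ENDMDL``, fixed columns), FASTA, and
tab-separated numeric tables (the latter are written with pandas by the
callers). Multi-frame trajectories are multi-model PDB files; binary
trajectory formats are deliberately unsupported.

Residue identity is ``(chain_id, res_seq, icode)`` under author numbering
throughout: every reported position in this package is the author-assigned
residue number, 1-based, exactly as printed in structure files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq

__all__ = [
    "Atom",
    "Structure",
    "SeqRecord",
    "PDBParseError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "read_fasta",
    "write_fasta",
]

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

VALID_RESIDUE_LETTERS = frozenset(THREE_TO_ONE.values()) | {"X"}


class PDBParseError(ValueError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """A PDB file contained no ATOM/HETATM records."""


@dataclass(slots=True)
class Atom:
    """One atom of a structure (coordinates in Å, author numbering)."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    coords: np.ndarray
    icode: str = ""
    element: str = ""
    hetero: bool = False
    model: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): element must be non-empty")
        if not self.hetero and self.res_name not in THREE_TO_ONE:
            # unknown residue on an ATOM record: keep, but mark hetero
            self.hetero = True

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class Structure:
    """An ordered collection of atoms, partitioned into models (frames).

    Model indices are contiguous from 1. Within one model an atom is
    uniquely identified by ``(chain_id, res_seq, icode, name)``.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def models(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.model, None)
        return sorted(seen)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def model(self, index: int) -> "Structure":
        """Single-model sub-structure for frame ``index`` (1-based)."""
        atoms = [a for a in self.atoms if a.model == index]
        if not atoms:
            raise KeyError(f"model {index} not present (have {self.models})")
        return Structure(id=f"{self.id}/model{index}", atoms=atoms)

    def split_models(self) -> dict[int, "Structure"]:
        """All frames as single-model sub-structures, in one pass.

        Per-frame loops should iterate this rather than calling
        :meth:`model` repeatedly, which rescans the whole atom list."""
        out: dict[int, Structure] = {}
        for a in self.atoms:
            sub = out.get(a.model)
            if sub is None:
                sub = out[a.model] = Structure(id=f"{self.id}/model{a.model}", atoms=[])
            sub.atoms.append(a)
        return dict(sorted(out.items()))

    def select(
        self,
        chain_id: str | None = None,
        res_seq: int | None = None,
        name: str | None = None,
        res_name: str | None = None,
        model: int | None = None,
        icode: str | None = None,
    ) -> list[Atom]:
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if res_seq is not None and a.res_seq != res_seq:
                continue
            if name is not None and a.name != name:
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            if model is not None and a.model != model:
                continue
            if icode is not None and a.icode != icode:
                continue
            out.append(a)
        return out

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.array([a.coords for a in src], dtype=float)

    def validate(self) -> None:
        """Check model contiguity and per-model atom-identity uniqueness."""
        models = self.models
        if models and models != list(range(1, len(models) + 1)):
            raise ValueError(f"model indices not contiguous from 1: {models}")
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.model, a.chain_id, a.res_seq, a.icode, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key}")
            seen.add(key)


@dataclass
class SeqRecord:
    """A 1-letter protein sequence with optional author numbering.

    ``numbering[i]`` is the author residue number of ``residues[i]``;
    when absent, positions are 1..len. ``breaks`` lists the 0-based
    indices *i* after which author numbering is discontinuous (a gap in
    the structure): scanning windows and docking windows never span a
    break.
    """

    id: str
    residues: str
    numbering: list[int] | None = None
    icodes: list[str] | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUE_LETTERS
        if bad:
            raise ValueError(f"record {self.id!r}: invalid residue letters {sorted(bad)}")
        if self.numbering is not None and len(self.numbering) != len(self.residues):
            raise ValueError(f"record {self.id!r}: numbering length mismatch")
        if self.icodes is not None and len(self.icodes) != len(self.residues):
            raise ValueError(f"record {self.id!r}: icodes length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, index: int) -> int:
        """Author position of 0-based ``index``."""
        if self.numbering is None:
            return index + 1
        return self.numbering[index]

    def index_of(self, position: int) -> int:
        """0-based index of author position ``position`` (first match)."""
        if self.numbering is None:
            if not 1 <= position <= len(self):
                raise KeyError(f"position {position} outside 1..{len(self)}")
            return position - 1
        try:
            return self.numbering.index(position)
        except ValueError:
            raise KeyError(f"position {position} not present in record {self.id!r}") from None

    @property
    def breaks(self) -> list[int]:
        if self.numbering is None:
            return []
        out = []
        for i in range(len(self.numbering) - 1):
            n1, n2 = self.numbering[i], self.numbering[i + 1]
            ic1 = self.icodes[i] if self.icodes else ""
            ic2 = self.icodes[i + 1] if self.icodes else ""
            contiguous = (n2 == n1 + 1 and ic2 == "") or (n2 == n1 and ic2 > ic1)
            if not contiguous:
                out.append(i)
        return out


# ---------------------------------------------------------------------------
# PDB

def _parse_atom_line(line: str, lineno: int, model: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        for ch in name:
            if ch.isalpha():
                element = ch.upper()
                break
    return Atom(
        serial=serial, name=name, res_name=res_name, chain_id=chain_id,
        res_seq=res_seq, icode=icode, coords=np.array([x, y, z]),
        element=element, hetero=line.startswith("HETATM"), model=model,
    )


def read_pdb(path: str | Path, id: str | None = None) -> Structure:
    """Read a single- or multi-model PDB file.

    One model per ``MODEL``/``ENDMDL`` block; a file with no MODEL records
    yields a single implicit model 1. Alternate locations other than
    '' / 'A' are skipped. Raises :class:`PDBParseError` naming the line on
    a malformed coordinate field and :class:`EmptyStructureError` when the
    file holds no atoms.
    """
    path = Path(path)
    atoms: list[Atom] = []
    model = 1
    model_seen = False
    model_map: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                model_seen = True
                try:
                    declared = int(line[10:14])
                except ValueError:
                    declared = len(model_map) + 1
                model_map[declared] = len(model_map) + 1
                model = model_map[declared]
            elif rec.startswith(("ATOM", "HETATM")):
                altloc = line[16] if len(line) > 16 else " "
                if altloc not in (" ", "A"):
                    continue
                atoms.append(_parse_atom_line(line.rstrip("\n"), lineno, model))
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    if not model_seen:
        for a in atoms:
            a.model = 1
    st = Structure(id=id or path.stem, atoms=atoms)
    st.validate()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ``structure`` as PDB v3.3; MODEL/ENDMDL blocks when multi-model."""
    path = Path(path)
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        for m in structure.models:
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for a in structure.atoms:
                if a.model != m:
                    continue
                rec = "HETATM" if a.hetero else "ATOM  "
                # atom-name column rule: names < 4 chars start in column 14
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"{rec}{a.serial:5d} {name:<4s} {a.res_name:<3s} "
                    f"{a.chain_id:1s}{a.res_seq:4d}{a.icode:1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def extract_sequence(structure: Structure, chain_id: str, model: int = 1) -> SeqRecord:
    """Sequence of one chain, in author numbering, from its CA atoms.

    Residues are ordered by ``(res_seq, icode)``; unknown residue codes
    become 'X' with a warning. Numbering gaps are preserved on the record
    so downstream window logic can refuse to span them.
    """
    cas = [
        a for a in structure.select(chain_id=chain_id, name="CA", model=model)
        if a.element != "CA"  # exclude calcium ions mis-hit by name
    ]
    if not cas:
        raise KeyError(f"chain {chain_id!r} has no CA atoms in model {model}")
    seen: dict[tuple[int, str], Atom] = {}
    for a in cas:
        seen.setdefault((a.res_seq, a.icode), a)
    ordered = sorted(seen.items(), key=lambda kv: kv[0])
    letters, numbering, icodes = [], [], []
    for (res_seq, icode), atom in ordered:
        one = THREE_TO_ONE.get(atom.res_name)
        if one is None:
            warnings.warn(f"unknown residue {atom.res_name} {chain_id}{res_seq}: using 'X'")
            one = "X"
        letters.append(one)
        numbering.append(res_seq)
        icodes.append(icode)
    return SeqRecord(
        id=f"{structure.id}_{chain_id}",
        residues="".join(letters),
        numbering=numbering,
        icodes=icodes if any(icodes) else None,
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; duplicate ids and empty sequences are errors."""
    records: list[SeqRecord] = []
    ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        ids.add(rec.id)
        records.append(SeqRecord(id=rec.id, residues=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrap."""
    recs = list(records)
    ids = [r.id for r in recs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate FASTA ids {sorted(dupes)}")
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in recs]
    SeqIO.write(bio, str(path), "fasta")
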