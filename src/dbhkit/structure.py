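"""Coordinate data model, strict PDB reading/writing and spatial queries.

The hierarchy is chains -> residues -> atoms with coordinates in Angstrom.
Residue numbering is 1-based precursor numbering throughout (the numbering
used for every residue citation in the package, e.g. His262, Cys528).
Metals, waters and ligands are carried as hetero residues addressed exactly
like polymer residues.

The PDB reader/writer deliberately supports a strict subset of the format
(ATOM/HETATM/TER/END, single model, no altlocs or insertion codes): modeled
and generated structures never need more, and strictness turns silent
coordinate corruption into loud errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "neighbor_search",
    "rigid_transform",
]

# Elements inferred from the leading alphabetic characters of an atom name.
# Two-letter element symbols used by the toolkit (metals, selenium).
_TWO_LETTER_ELEMENTS = {"CU", "ZN", "FE", "MG", "MN", "NA", "CL", "SE", "CA"}

WATER_NAMES = {"HOH", "WAT"}
METAL_NAMES = {"CU", "ZN", "FE", "MG", "MN", "NA", "CA"}


class PDBFormatError(ValueError):
    """Raised for malformed or unsupported PDB content."""


def element_from_name(name: str, res_name: str = "") -> str:
    """Infer the chemical element from an atom label.

    Hetero entries whose residue name is itself a metal symbol (e.g. CU)
    take that symbol; otherwise the first alphabetic character of the atom
    name is the element (CA -> C, ND1 -> N, SG -> S, OE1 -> O).
    """
    stripped = name.strip().upper()
    if not stripped:
        raise ValueError("atom name must be non-empty")
    if res_name.strip().upper() in METAL_NAMES:
        return res_name.strip().upper()
    if stripped in _TWO_LETTER_ELEMENTS and res_name.strip().upper() in (
        stripped,
        "",
    ):
        return stripped
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class Atom:
    name: str
    coords: np.ndarray
    element: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("atom name must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = element_from_name(self.name)


@dataclass
class Residue:
    chain_id: str
    seq_pos: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq_pos < 1:
            raise ValueError(f"seq_pos must be >= 1, got {self.seq_pos}")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.chain_id}{self.seq_pos}"
            )

    @property
    def is_hetero(self) -> bool:
        return any(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name} in residue {self.res_name}{self.seq_pos}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def add_atom(self, atom: Atom) -> None:
        if self.has_atom(atom.name):
            raise ValueError(
                f"duplicate atom {atom.name} in residue {self.chain_id}{self.seq_pos}"
            )
        self.atoms.append(atom)


class Structure:
    """Ordered chains of residues plus hetero entities (metals/waters/ligands)."""

    def __init__(self, residues: Iterable[Residue] = ()) -> None:
        self._chains: dict[str, list[Residue]] = {}
        for res in residues:
            self.add_residue(res)

    # -- construction -----------------------------------------------------
    def add_residue(self, res: Residue) -> None:
        chain = self._chains.setdefault(res.chain_id, [])
        if not res.is_hetero:
            polymer = [r for r in chain if not r.is_hetero]
            if polymer and res.seq_pos <= polymer[-1].seq_pos:
                raise ValueError(
                    f"seq_pos must strictly increase within chain {res.chain_id}: "
                    f"{res.seq_pos} after {polymer[-1].seq_pos}"
                )
        if any(r.seq_pos == res.seq_pos and r.is_hetero == res.is_hetero for r in chain):
            raise ValueError(
                f"duplicate residue ({res.chain_id}, {res.seq_pos}) in structure"
            )
        chain.append(res)

    # -- access -----------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def chain(self, chain_id: str) -> list[Residue]:
        return self._chains[chain_id]

    def polymer_residues(self, chain_id: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain_id) if not r.is_hetero]

    def het_residues(self, chain_id: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain_id) if r.is_hetero]

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is not None:
            return list(self._chains.get(chain_id, []))
        return [r for ch in self._chains.values() for r in ch]

    def residue(self, chain_id: str, seq_pos: int) -> Residue:
        for r in self._chains.get(chain_id, []):
            if r.seq_pos == seq_pos:
                return r
        raise KeyError(f"no residue ({chain_id}, {seq_pos})")

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def atom_coords(self) -> np.ndarray:
        coords = [a.coords for _, a in self.atoms()]
        return np.array(coords) if coords else np.empty((0, 3))

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def sequence(self, chain_id: str) -> str:
        from .seqstats import three_to_one

        return "".join(
            three_to_one(r.res_name, default="X") for r in self.polymer_residues(chain_id)
        )

    def copy(self) -> "Structure":
        out = Structure()
        for res in self.residues():
            out.add_residue(
                Residue(
                    res.chain_id,
                    res.seq_pos,
                    res.res_name,
                    [
                        Atom(a.name, a.coords.copy(), a.element, a.is_hetero)
                        for a in res.atoms
                    ],
                )
            )
        return out

    def renamed_chain(self, old: str, new: str) -> "Structure":
        out = Structure()
        for res in self.residues():
            cid = new if res.chain_id == old else res.chain_id
            out.add_residue(
                Residue(
                    cid,
                    res.seq_pos,
                    res.res_name,
                    [
                        Atom(a.name, a.coords.copy(), a.element, a.is_hetero)
                        for a in res.atoms
                    ],
                )
            )
        return out

    def merged(self, other: "Structure") -> "Structure":
        shared = set(self.chain_ids) & set(other.chain_ids)
        if shared:
            raise ValueError(f"chain id collision: {sorted(shared)}")
        out = self.copy()
        for res in other.copy().residues():
            out.add_residue(res)
        return out


# -- spatial queries ------------------------------------------------------

def neighbor_search(
    structure: Structure,
    query: Sequence[Atom] | np.ndarray,
    radius: float,
) -> list[tuple[Residue, Atom]]:
    """Atoms of `structure` within `radius` (inclusive) of any query atom.

    Backed by a k-d tree; contractually identical to the all-pairs scan.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    entries = list(structure.atoms())
    if not entries:
        return []
    if isinstance(query, np.ndarray):
        qcoords = np.atleast_2d(query)
    else:
        qcoords = np.array([a.coords for a in query])
    if qcoords.size == 0:
        return []
    coords = np.array([a.coords for _, a in entries])
    tree = cKDTree(coords)
    hits: set[int] = set()
    for idx_list in tree.query_ball_point(qcoords, r=radius):
        hits.update(idx_list)
    return [entries[i] for i in sorted(hits)]


def rigid_transform(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Apply x -> R x + t to every atom, returning a new Structure."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    if rotation.shape != (3, 3) or translation.shape != (3,):
        raise ValueError("rotation must be 3x3 and translation a 3-vector")
    out = structure.copy()
    for _, atom in out.atoms():
        atom.coords = rotation @ atom.coords + translation
    return out


# -- PDB I/O ---------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBFormatError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records from a fixed-column PDB file."""
    structure = Structure()
    current: Residue | None = None
    seen: set[tuple[str, int, str, bool]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"line {lineno}: truncated coordinate record")
            altloc = line[16]
            icode = line[26]
            if altloc != " ":
                raise PDBFormatError(
                    f"line {lineno}: alternate location codes are not supported"
                )
            if icode != " ":
                raise PDBFormatError(
                    f"line {lineno}: insertion codes are not supported"
                )
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21]
            if chain_id == " ":
                chain_id = "A"
            try:
                seq_pos = int(line[22:26])
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: malformed residue number {line[22:26].strip()!r}"
                ) from None
            x = _parse_float(line[30:38], "x coordinate", lineno)
            y = _parse_float(line[38:46], "y coordinate", lineno)
            z = _parse_float(line[46:54], "z coordinate", lineno)
            element = line[76:78].strip() if len(line) >= 78 else ""
            is_het = record == "HETATM"
            key = (chain_id, seq_pos, name, is_het)
            if key in seen:
                raise PDBFormatError(
                    f"line {lineno}: duplicate atom {name} in residue "
                    f"{chain_id}{seq_pos}"
                )
            seen.add(key)
            atom = Atom(
                name,
                np.array([x, y, z]),
                element or element_from_name(name, res_name),
                is_hetero=is_het,
            )
            if (
                current is None
                or current.chain_id != chain_id
                or current.seq_pos != seq_pos
                or current.is_hetero != is_het
                or current.res_name != res_name
            ):
                if current is not None:
                    structure.add_residue(current)
                current = Residue(chain_id, seq_pos, res_name, [])
            current.add_atom(atom)
    if current is not None:
        structure.add_residue(current)
    return structure


def _format_atom_name(name: str, element: str) -> str:
    # Single-character elements start in column 14; wider names fill 13-16.
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path) -> None:
    """Write standard fixed-column ATOM/HETATM records with TER between chains."""
    if len(structure.chain_ids) > 62:
        raise ValueError("more than 62 chains cannot be written to PDB")
    lines: list[str] = []
    serial = 1
    for chain_id in structure.chain_ids:
        wrote_polymer = False
        for res in structure.residues(chain_id):
            if res.seq_pos > 9999:
                raise ValueError(
                    f"residue number {res.seq_pos} exceeds the PDB format limit"
                )
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                x, y, z = atom.coords
                if max(abs(x), abs(y), abs(z)) > 9999.999:
                    raise ValueError("coordinate exceeds PDB fixed-column range")
                lines.append(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.res_name:<3s} {chain_id}{res.seq_pos:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
            if not res.is_hetero:
                wrote_polymer = True
        if wrote_polymer:
            lines.append(f"TER   {serial:>5d}")
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
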