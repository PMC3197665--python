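"""Sequence composition statistics and MSA conservation profiling.

The charge model is the integer surface-charge count used throughout the
package: Asp+Glu carry -1 each, Arg+Lys +1 each, His is neutral, and no pKa
model is applied, so net charge = (R+K) - (D+E) in elementary charges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from io import StringIO

from Bio import AlignIO, SeqIO

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "CompositionReport",
    "ConservationProfile",
    "composition",
    "conservation_profile",
    "pairwise_identity",
    "read_fasta",
    "read_alignment",
    "load_dbh_sequence",
    "one_to_three",
    "three_to_one",
]

# Average (not monoisotopic) residue masses in g/mol, to 2 decimals.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
WATER_MASS = 18.02

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


def one_to_three(letter: str) -> str:
    return _ONE_TO_THREE[letter.upper()]


def three_to_one(code: str, default: str | None = None) -> str:
    code = code.upper()
    if code in _THREE_TO_ONE:
        return _THREE_TO_ONE[code]
    if default is not None:
        return default
    raise KeyError(f"unknown residue code {code!r}")


@dataclass(frozen=True)
class CompositionReport:
    length: int
    n_cys: int
    n_neg: int        # Asp + Glu
    n_pos: int        # Arg + Lys
    net_charge: int   # n_pos - n_neg, elementary charges
    molar_mass: float  # g/mol, average isotopic

    def as_dict(self) -> dict:
        return {
            "length": self.length,
            "n_cys": self.n_cys,
            "n_neg": self.n_neg,
            "n_pos": self.n_pos,
            "net_charge": self.net_charge,
            "molar_mass": round(self.molar_mass, 2),
        }


@dataclass(frozen=True)
class ConservationProfile:
    fully_conserved: tuple[bool, ...]
    n_sequences: int
    n_columns: int

    @property
    def count_conserved(self) -> int:
        return sum(self.fully_conserved)


def composition(sequence: str) -> CompositionReport:
    """Composition counts and average molar mass of an amino-acid sequence."""
    sequence = sequence.upper()
    for i, ch in enumerate(sequence):
        if ch not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"non-standard residue {ch!r} at position {i + 1}")
    counts = Counter(sequence)
    n_neg = counts["D"] + counts["E"]
    n_pos = counts["R"] + counts["K"]
    mass = sum(AVERAGE_RESIDUE_MASS[ch] for ch in sequence)
    if sequence:
        mass += WATER_MASS
    return CompositionReport(
        length=len(sequence),
        n_cys=counts["C"],
        n_neg=n_neg,
        n_pos=n_pos,
        net_charge=n_pos - n_neg,
        molar_mass=mass,
    )


def conservation_profile(msa: list[str]) -> ConservationProfile:
    """Per-column full-conservation flags for an aligned set of sequences.

    A column is fully conserved iff every row carries the same non-gap
    letter; a gap anywhere in the column breaks conservation.
    """
    if not msa:
        return ConservationProfile((), 0, 0)
    width = len(msa[0])
    for i, row in enumerate(msa):
        if len(row) != width:
            raise ValueError(
                f"ragged alignment: row {i + 1} has length {len(row)}, expected {width}"
            )
    flags = []
    for col in range(width):
        letters = {row[col].upper() for row in msa}
        flags.append(len(letters) == 1 and "-" not in letters)
    return ConservationProfile(tuple(flags), len(msa), width)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where both aligned rows are non-gap."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    both = [
        (a.upper(), b.upper())
        for a, b in zip(seq_a, seq_b)
        if a != "-" and b != "-"
    ]
    if not both:
        return 0.0
    same = sum(a == b for a, b in both)
    return 100.0 * same / len(both)


# -- readers ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file, keyed by record id (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment(path, fmt: str = "fasta") -> list[str]:
    """Aligned rows from a FASTA or Clustal alignment file."""
    alignment = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in alignment]


def load_dbh_sequence() -> str:
    """The 617-residue human dopamine beta-hydroxylase precursor (P09172)."""
    data = resources.files("dbhkit.data").joinpath("P09172.fasta").read_text()
    rec = next(SeqIO.parse(StringIO(data), "fasta"))
    return str(rec.seq)


# First residue of the soluble enzyme: the precursor's N-terminal
# signal-anchor segment (cytoplasmic tail plus the hydrophobic stretch
# ending at residue 38) is absent from the secreted form.
DBH_SOLUBLE_START = 39


def load_dbh_soluble_sequence() -> str:
    """The soluble-form chain: the precursor minus its signal-anchor (1-38)."""
    return load_dbh_sequence()[DBH_SOLUBLE_START - 1:]
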