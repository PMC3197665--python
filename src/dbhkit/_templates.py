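"""Idealized heavy-atom side-chain templates in internal coordinates.

Each side-chain atom is defined by (name, a, b, c, bond, angle, torsion):
the atom is placed at distance `bond` from c, with angle(b, c, atom) =
`angle` degrees and dihedral(a, b, c, atom) = `torsion` degrees, where a, b
and c are previously placed atoms of the same residue.  Rotamers are fixed
idealized ones (chi1 = -60 style stubs); the templates define connectivity
and plausible geometry, not a physical rotamer library.
"""

from __future__ import annotations

# (name, a, b, c, bond, angle, torsion)
_Row = tuple[str, str, str, str, float, float, float]

_CB: _Row = ("CB", "N", "C", "CA", 1.53, 110.5, 122.6)

SIDECHAIN_TEMPLATES: dict[str, list[_Row]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "N", "CA", "CB", 1.417, 110.8, -60.0)],
    "CYS": [_CB, ("SG", "N", "CA", "CB", 1.808, 114.4, -60.0)],
    "THR": [
        _CB,
        ("OG1", "N", "CA", "CB", 1.433, 109.6, -60.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, 60.0),
    ],
    "VAL": [
        _CB,
        ("CG1", "N", "CA", "CB", 1.527, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, -60.0),
    ],
    "LEU": [
        _CB,
        ("CG", "N", "CA", "CB", 1.530, 116.3, 180.0),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, 60.0),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, 180.0),
    ],
    "ILE": [
        _CB,
        ("CG1", "N", "CA", "CB", 1.530, 110.4, 180.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, 180.0),
    ],
    "MET": [
        _CB,
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, 180.0),
        ("CE", "CB", "CG", "SD", 1.791, 100.6, 180.0),
    ],
    "PRO": [
        _CB,
        ("CG", "N", "CA", "CB", 1.492, 104.5, -30.0),
        ("CD", "CA", "CB", "CG", 1.503, 106.1, 30.0),
    ],
    "PHE": [
        _CB,
        ("CG", "N", "CA", "CB", 1.502, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.391, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.391, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.391, 120.8, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.391, 120.8, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", "N", "CA", "CB", 1.502, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.391, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.391, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.391, 120.8, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.391, 120.8, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.377, 119.9, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", "N", "CA", "CB", 1.498, 113.6, 180.0),
        ("CD1", "CA", "CB", "CG", 1.365, 127.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.433, 126.6, -90.0),
        ("NE1", "CB", "CG", "CD1", 1.375, 110.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
    ],
    "ASP": [
        _CB,
        ("CG", "N", "CA", "CB", 1.516, 113.1, 180.0),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0),
    ],
    "ASN": [
        _CB,
        ("CG", "N", "CA", "CB", 1.516, 113.1, 180.0),
        ("OD1", "CA", "CB", "CG", 1.231, 120.9, 0.0),
        ("ND2", "CA", "CB", "CG", 1.328, 116.5, 180.0),
    ],
    "GLU": [
        _CB,
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0),
    ],
    "GLN": [
        _CB,
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.231, 120.9, 0.0),
        ("NE2", "CB", "CG", "CD", 1.328, 116.5, 180.0),
    ],
    "LYS": [
        _CB,
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, 180.0),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0),
    ],
    "ARG": [
        _CB,
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "HIS": [
        _CB,
        ("CG", "N", "CA", "CB", 1.497, 113.8, 180.0),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, 90.0),
        ("CD2", "CA", "CB", "CG", 1.356, 131.0, -90.0),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.0, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.0, 180.0),
    ],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def residue_heavy_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy-atom names of the idealized template for a 3-letter code."""
    res_name = res_name.upper()
    if res_name not in SIDECHAIN_TEMPLATES:
        raise KeyError(f"unknown residue type {res_name!r}")
    return BACKBONE_ATOMS + tuple(row[0] for row in SIDECHAIN_TEMPLATES[res_name])
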