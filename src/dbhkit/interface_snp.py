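"""Oligomer-interface characterization and SNP structural-context mapping.

Interfaces are described by four interaction classes — interchain hydrogen
bonds, salt bridges (charged groups within 7 A), electrostatic contacts
(charged groups strictly under 4 A, a subset of the salt bridges) and
hydrophobic contacts (side-chain carbon-carbon pairs) — reported
independently, so a residue may appear in several classes.  A missense
variant's context is its 6 A any-heavy-atom neighborhood (the variant
residue included), distance to the nearest metal, interface membership and
surface exposure, condensed into a significance call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._templates import SIDECHAIN_TEMPLATES
from .assembly import place_atom
from .constraints import AnalysisParams, ConstraintSet
from .geometry import hbonds
from .structure import Atom, Residue, Structure, METAL_NAMES, WATER_NAMES

__all__ = [
    "InterfaceReport",
    "SnpContext",
    "salt_bridges",
    "electrostatic_contacts",
    "hydrophobic_contacts",
    "interface_report",
    "interface_table",
    "mutate_residue",
    "neighborhood",
    "relative_exposure",
    "snp_context",
    "snp_table",
    "parse_variant",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
# His is excluded from the basic set by default; enable via include_his.
HIS_ATOMS = {"HIS": ("ND1", "NE2")}

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}

# Theoretical maximum accessible areas (Gly-X-Gly reference), A^2.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _charged_atoms(
    structure: Structure, include_his: bool = False
) -> tuple[list[tuple[Residue, Atom]], list[tuple[Residue, Atom]]]:
    acidic = []
    basic = []
    basic_table = dict(BASIC_ATOMS)
    if include_his:
        basic_table.update(HIS_ATOMS)
    for res, atom in structure.atoms():
        names = ACIDIC_ATOMS.get(res.res_name.upper())
        if names and atom.name in names:
            acidic.append((res, atom))
        names = basic_table.get(res.res_name.upper())
        if names and atom.name in names:
            basic.append((res, atom))
    return acidic, basic


def _charged_pairs(
    structure: Structure,
    chains: set[str] | None,
    include_his: bool,
) -> list[tuple[Residue, Residue, float]]:
    """Interchain acidic/basic residue pairs with their closest group-atom
    distance (unfiltered by cutoff)."""
    acidic, basic = _charged_atoms(structure, include_his)
    best: dict[tuple[tuple[str, int], tuple[str, int]], tuple[Residue, Residue, float]] = {}
    for res_a, atom_a in acidic:
        for res_b, atom_b in basic:
            if res_a.chain_id == res_b.chain_id:
                continue
            if chains is not None and not (
                res_a.chain_id in chains and res_b.chain_id in chains
            ):
                continue
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            key = ((res_a.chain_id, res_a.seq_pos), (res_b.chain_id, res_b.seq_pos))
            if key not in best or d < best[key][2]:
                best[key] = (res_a, res_b, d)
    return list(best.values())


def salt_bridges(
    structure: Structure,
    chains: set[str] | None = None,
    cutoff: float = 7.0,
    include_his: bool = False,
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Interchain acidic-O / basic-N residue pairs within `cutoff` (inclusive)."""
    out = []
    for res_a, res_b, d in _charged_pairs(structure, chains, include_his):
        if d <= cutoff:
            out.append(
                (
                    (res_a.chain_id, res_a.seq_pos, res_a.res_name),
                    (res_b.chain_id, res_b.seq_pos, res_b.res_name),
                    d,
                )
            )
    out.sort(key=lambda r: (r[0], r[1]))
    return out


def electrostatic_contacts(
    structure: Structure,
    chains: set[str] | None = None,
    cutoff: float = 4.0,
    include_his: bool = False,
) -> dict[str, list[int]]:
    """Charged-group pairs at strictly < `cutoff`; residues grouped per chain."""
    per_chain: dict[str, set[int]] = {}
    for res_a, res_b, d in _charged_pairs(structure, chains, include_his):
        if d < cutoff:
            per_chain.setdefault(res_a.chain_id, set()).add(res_a.seq_pos)
            per_chain.setdefault(res_b.chain_id, set()).add(res_b.seq_pos)
    return {c: sorted(v) for c, v in sorted(per_chain.items())}


def _sidechain_carbons(res: Residue) -> list[Atom]:
    return [
        a for a in res.atoms
        if a.element == "C" and a.name not in ("C", "CA")
    ]


def hydrophobic_contacts(
    structure: Structure,
    chains: set[str] | None = None,
    cc_cutoff: float = 4.0,
) -> dict[str, list[int]]:
    """Interchain side-chain carbon-carbon contacts between hydrophobic residues."""
    entries = []
    for res in structure.residues():
        if res.res_name.upper() not in HYDROPHOBIC_RESIDUES:
            continue
        if chains is not None and res.chain_id not in chains:
            continue
        carbons = _sidechain_carbons(res)
        if carbons:
            entries.append((res, np.array([a.coords for a in carbons])))
    per_chain: dict[str, set[int]] = {}
    for i in range(len(entries)):
        res_i, ci = entries[i]
        for j in range(i + 1, len(entries)):
            res_j, cj = entries[j]
            if res_i.chain_id == res_j.chain_id:
                continue
            if cdist(ci, cj).min() <= cc_cutoff:
                per_chain.setdefault(res_i.chain_id, set()).add(res_i.seq_pos)
                per_chain.setdefault(res_j.chain_id, set()).add(res_j.seq_pos)
    return {c: sorted(v) for c, v in sorted(per_chain.items())}


@dataclass
class InterfaceReport:
    interchain_hbond: dict[str, list[int]]
    salt_bridge: dict[str, list[int]]
    electrostatic: dict[str, list[int]]
    hydrophobic: dict[str, list[int]]
    salt_bridge_pairs: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]
    hbond_pairs: list
    domain_share_unique: dict[str, float]
    domain_share_occurrences: dict[str, float]

    @property
    def union(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for table in (
            self.interchain_hbond,
            self.salt_bridge,
            self.electrostatic,
            self.hydrophobic,
        ):
            for chain, positions in table.items():
                out.update((chain, p) for p in positions)
        return out


def interface_report(structure: Structure, cs: ConstraintSet) -> InterfaceReport:
    """All four interaction classes plus per-domain interface shares.

    Classes are reported independently (a residue may appear in several).
    Domain shares are given both over unique sequence positions and over
    per-chain occurrences.
    """
    polymer_chains = {
        c for c in structure.chain_ids if structure.polymer_residues(c)
    }
    if len(polymer_chains) < 2:
        raise ValueError("interface analysis needs at least 2 chains")
    params = cs.params

    hb_pairs = [
        (donor, acceptor, d, ang)
        for donor, acceptor, d, ang in hbonds(structure, params)
        if donor[0] != acceptor[0]
    ]
    hb: dict[str, set[int]] = {}
    for donor, acceptor, _, _ in hb_pairs:
        hb.setdefault(donor[0], set()).add(donor[1])
        hb.setdefault(acceptor[0], set()).add(acceptor[1])

    sb_pairs = salt_bridges(structure, None, params.salt_bridge_cutoff)
    sb: dict[str, set[int]] = {}
    for a, b, _ in sb_pairs:
        sb.setdefault(a[0], set()).add(a[1])
        sb.setdefault(b[0], set()).add(b[1])

    report = InterfaceReport(
        interchain_hbond={c: sorted(v) for c, v in sorted(hb.items())},
        salt_bridge={c: sorted(v) for c, v in sorted(sb.items())},
        electrostatic=electrostatic_contacts(
            structure, None, params.electrostatic_cutoff
        ),
        hydrophobic=hydrophobic_contacts(
            structure, None, params.hydrophobic_cc_cutoff
        ),
        salt_bridge_pairs=sb_pairs,
        hbond_pairs=hb_pairs,
        domain_share_unique={},
        domain_share_occurrences={},
    )
    union = report.union
    if union and cs.domain_ranges:
        unique_positions = {pos for _, pos in union}
        for name in cs.domain_ranges:
            in_dom_u = sum(
                1 for pos in unique_positions if cs.domain_of(pos) == name
            )
            in_dom_o = sum(1 for _, pos in union if cs.domain_of(pos) == name)
            report.domain_share_unique[name] = in_dom_u / len(unique_positions)
            report.domain_share_occurrences[name] = in_dom_o / len(union)
    return report


def interface_table(report: InterfaceReport) -> pd.DataFrame:
    """Four-column rendering of an InterfaceReport (one class per column)."""

    def fmt(table: dict[str, list[int]]) -> str:
        return "; ".join(
            f"{chain}: {','.join(str(p) for p in positions)}"
            for chain, positions in table.items()
        )

    return pd.DataFrame(
        {
            "Interchain H-bonds": [fmt(report.interchain_hbond)],
            "Salt Bridge": [fmt(report.salt_bridge)],
            "Electrostatic Interactions": [fmt(report.electrostatic)],
            "Hydrophobic Interactions": [fmt(report.hydrophobic)],
        }
    )


# -- mutation --------------------------------------------------------------

def mutate_residue(
    structure: Structure, pos: int, chain: str, new_res3: str
) -> Structure:
    """Rename a residue and rebuild its side chain as an idealized stub.

    The backbone is untouched; the old side chain is removed and the new
    type's template atoms are grown from the existing N/CA/C positions.
    """
    new_res3 = new_res3.upper()
    if new_res3 not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"unknown residue type {new_res3!r}")
    out = structure.copy()
    res = out.residue(chain, pos)
    if res.res_name.upper() == new_res3:
        return out
    backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
    if len([a for a in backbone if a.name in ("N", "CA", "C")]) < 3:
        raise ValueError(f"residue {chain}{pos} lacks a complete backbone")
    res.res_name = new_res3
    res.atoms = backbone
    local = {a.name: a.coords for a in backbone}
    for name, a, b, c, bond, angle, torsion in SIDECHAIN_TEMPLATES[new_res3]:
        coords = place_atom(local[a], local[b], local[c], bond, angle, torsion)
        local[name] = coords
        res.add_atom(Atom(name, coords))
    return out


# -- neighborhood and SNP context -----------------------------------------

def neighborhood(
    structure: Structure,
    pos: int,
    chain: str,
    radius: float = 6.0,
) -> list[tuple[str, int, str]]:
    """Polymer residues (self included) with any heavy atom within `radius`
    of any heavy atom of the target residue."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    target = structure.residue(chain, pos)
    tcoords = np.array([a.coords for a in target.atoms])
    out = []
    for res in structure.residues():
        if res.is_hetero:
            continue
        coords = np.array([a.coords for a in res.atoms])
        if cdist(tcoords, coords).min() <= radius:
            out.append((res.chain_id, res.seq_pos, res.res_name))
    return sorted(out)


def relative_exposure(structure: Structure, probe: float = 1.4) -> dict[tuple[str, int], float]:
    """Shrake-Rupley accessible area per residue relative to its Gly-X-Gly
    maximum (probe 1.4 A)."""
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley
    from .structure import write_pdb
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        path = fh.name
    try:
        write_pdb(structure, path)
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure("s", path)
        ShrakeRupley(probe_radius=probe).compute(bio, level="R")
        out = {}
        for model in bio:
            for bio_chain in model:
                for bio_res in bio_chain:
                    name = bio_res.get_resname().upper()
                    if name not in MAX_ASA:
                        continue
                    key = (bio_chain.id, bio_res.id[1])
                    out[key] = float(bio_res.sasa) / MAX_ASA[name]
        return out
    finally:
        os.unlink(path)


@dataclass
class SnpContext:
    variant: tuple[int, str, str]             # pos, ref one-letter, alt one-letter
    chain: str
    neighborhood: list[tuple[str, int, str]]  # self included
    dist_to_nearest_metal: float              # inf when no metal present
    dist_to_interface: float                  # 0 when the variant is interfacial
    interface_flag: bool
    surface_flag: bool
    rel_exposure: float
    significance: str


def parse_variant(text: str) -> tuple[int, str, str, str]:
    """Parse 'G482R' or 'G482R:A' into (pos, ref, alt, chain)."""
    chain = "A"
    if ":" in text:
        text, chain = text.split(":", 1)
    ref, alt = text[0].upper(), text[-1].upper()
    pos = int(text[1:-1])
    return pos, ref, alt, chain


def snp_context(
    structure: Structure,
    cs: ConstraintSet,
    interface: InterfaceReport | None,
    variant: tuple[int, str, str],
    chain: str = "A",
) -> SnpContext:
    """Structural context and significance call for one missense variant.

    Significance (first matching rule):
    active-site-proximal  — a neighborhood residue is a metal ligand, or the
                            variant is within params.active_site_metal_dist
                            of a metal;
    interface-proximal    — the variant or a neighbor is in the interface
                            union;
    surface-cysteine-risk — the substitution introduces Cys at a surface-
                            exposed position (risk of non-native interchain
                            disulfides);
    likely-neutral        — none of the above.
    """
    pos, ref, alt = variant
    params = cs.params
    res = structure.residue(chain, pos)  # raises KeyError if absent
    from .seqstats import three_to_one

    if ref and three_to_one(res.res_name, default="X") != ref.upper():
        raise ValueError(
            f"reference mismatch at {chain}{pos}: structure has {res.res_name}"
        )
    nbrs = neighborhood(structure, pos, chain, params.snp_radius)

    # distance to nearest metal, over the variant's heavy atoms
    vcoords = np.array([a.coords for a in res.atoms])
    metal_coords = [
        a.coords for r, a in structure.atoms()
        if a.is_hetero and a.element.upper() in METAL_NAMES
    ]
    if metal_coords:
        dist_metal = float(cdist(vcoords, np.array(metal_coords)).min())
    else:
        dist_metal = math.inf

    # metal-ligand residues: constrained positions plus structural ligands
    ligand_positions = {
        p for site in cs.metal_sites for (p, _, _) in site.ligands
    }
    structural_ligands: set[tuple[str, int]] = set()
    if metal_coords:
        for r in structure.residues():
            if r.is_hetero:
                continue
            coords = np.array([a.coords for a in r.atoms])
            if cdist(coords, np.array(metal_coords)).min() <= params.metal_ligand_cutoff:
                structural_ligands.add((r.chain_id, r.seq_pos))

    union = interface.union if interface is not None else set()
    interface_flag = any((c, p) in union for c, p, _ in nbrs)
    if union:
        ucoords = []
        for c, p in union:
            try:
                ucoords.extend(a.coords for a in structure.residue(c, p).atoms)
            except KeyError:
                continue
        dist_interface = float(cdist(vcoords, np.array(ucoords)).min()) if ucoords else math.inf
    else:
        dist_interface = math.inf

    exposure = relative_exposure(structure).get((chain, pos), 0.0)
    surface_flag = exposure >= params.surface_rel_exposure

    neighbor_is_ligand = any(
        p in ligand_positions or (c, p) in structural_ligands
        for c, p, _ in nbrs
    )
    if neighbor_is_ligand or dist_metal <= params.active_site_metal_dist:
        significance = "active-site-proximal"
    elif interface_flag:
        significance = "interface-proximal"
    elif alt.upper() == "C" and surface_flag:
        significance = "surface-cysteine-risk"
    else:
        significance = "likely-neutral"

    return SnpContext(
        variant=(pos, ref, alt),
        chain=chain,
        neighborhood=nbrs,
        dist_to_nearest_metal=dist_metal,
        dist_to_interface=dist_interface,
        interface_flag=interface_flag,
        surface_flag=surface_flag,
        rel_exposure=exposure,
        significance=significance,
    )


def snp_table(contexts: list[SnpContext]) -> pd.DataFrame:
    """Two-column table: the substitution and its 6 A neighborhood."""
    rows = []
    for ctx in contexts:
        pos, ref, alt = ctx.variant
        from .seqstats import one_to_three

        rows.append(
            {
                "SNP": f"{one_to_three(ref).capitalize()}{pos}→"
                       f"{one_to_three(alt).capitalize()}{pos}",
                "Residues in 6 Å radius": ",".join(
                    f"{r.capitalize()}{p}" for _, p, r in ctx.neighborhood
                ),
                "Significance": ctx.significance,
            }
        )
    return pd.DataFrame(rows)
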