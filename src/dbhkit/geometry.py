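"""Structure assessment: disulfides, metal sites, Ramachandran, H-bonds,
secondary structure and steric clashes.

All criteria are defined on heavy atoms (hydrogens are absent by
convention).  Distance comparisons are closed (<= cutoff) unless a
criterion is explicitly strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .assembly import dihedral, extract_torsions
from .constraints import AnalysisParams, ConstraintSet, MetalSiteSpec
from .structure import Atom, Residue, Structure, METAL_NAMES, WATER_NAMES

__all__ = [
    "DisulfideReport",
    "MetalSiteReport",
    "RamaReport",
    "find_disulfides",
    "validate_disulfides",
    "place_metal",
    "analyze_metal_site",
    "ramachandran",
    "hbonds",
    "assign_ss",
    "ss_agreement",
    "clashes",
]


# -- disulfides ------------------------------------------------------------

@dataclass
class DisulfideReport:
    detected: list[tuple[tuple[str, int], tuple[str, int], float]]
    statuses: dict[tuple[int, int], str]        # hard constraints
    soft_statuses: dict[tuple[int, int], str]   # reported separately
    achieved: dict[tuple[int, int], float | None]

    @property
    def all_hard_satisfied(self) -> bool:
        return all(s == "satisfied" for s in self.statuses.values())


def find_disulfides(
    structure: Structure, max_sg_sg: float = 2.5
) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
    """All SG-SG pairs of distinct residues within the cutoff (inclusive)."""
    sgs = [
        (res, atom)
        for res, atom in structure.atoms()
        if atom.name == "SG" and res.res_name.upper() == "CYS"
    ]
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            ri, ai = sgs[i]
            rj, aj = sgs[j]
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d <= max_sg_sg:
                out.append(((ri.chain_id, ri.seq_pos), (rj.chain_id, rj.seq_pos), d))
    return out


def validate_disulfides(
    structure: Structure,
    cs: ConstraintSet,
    tolerance: float | None = None,
) -> DisulfideReport:
    """Map each disulfide constraint to satisfied / violated / missing-atom.

    A bond is satisfied when the SG-SG distance is within tolerance of the
    target (default: params.ss_bond_target +/- ss_bond_tolerance).  Soft
    constraints are reported separately and never fail the structure.
    Interchain constraints are expanded over every chain pair present.
    """
    params = cs.params
    tol = params.ss_bond_tolerance if tolerance is None else tolerance
    chains = [c for c in structure.chain_ids if structure.polymer_residues(c)]
    statuses: dict[tuple[int, int], str] = {}
    soft: dict[tuple[int, int], str] = {}
    achieved: dict[tuple[int, int], float | None] = {}

    def measure(res_a: Residue | None, res_b: Residue | None) -> tuple[str, float | None]:
        if (
            res_a is None or res_b is None
            or not res_a.has_atom("SG") or not res_b.has_atom("SG")
        ):
            return "missing-atom", None
        d = float(np.linalg.norm(res_a.atom("SG").coords - res_b.atom("SG").coords))
        ok = abs(d - params.ss_bond_target) <= tol
        return ("satisfied" if ok else "violated"), d

    def get(chain: str, pos: int) -> Residue | None:
        try:
            res = structure.residue(chain, pos)
        except KeyError:
            return None
        return res if res.res_name.upper() == "CYS" else None

    for ss in cs.disulfides:
        key = (ss.pos_i, ss.pos_j)
        if ss.scope == "intrachain":
            # satisfied if formed in any chain carrying both positions
            status, dist = "missing-atom", None
            for chain in chains:
                st, d = measure(get(chain, ss.pos_i), get(chain, ss.pos_j))
                if st == "satisfied" or (st == "violated" and status == "missing-atom"):
                    status, dist = st, d
                if status == "satisfied":
                    break
        else:
            status, dist = "missing-atom", None
            if len(chains) >= 2:
                pairs = (
                    [ss.chain_pair]
                    if ss.chain_pair
                    else [
                        (a, b)
                        for i, a in enumerate(chains)
                        for b in chains[i + 1:]
                    ]
                )
                for ca, cb in pairs:
                    st, d = measure(get(ca, ss.pos_i), get(cb, ss.pos_j))
                    if st == "satisfied" or (st == "violated" and status == "missing-atom"):
                        status, dist = st, d
                    if status == "satisfied":
                        break
        achieved[key] = dist
        (soft if ss.soft else statuses)[key] = status

    return DisulfideReport(
        detected=find_disulfides(structure, params.ss_bond_target + tol),
        statuses=statuses,
        soft_statuses=soft,
        achieved=achieved,
    )


# -- metal sites -----------------------------------------------------------

@dataclass
class MetalSiteReport:
    metal: tuple[str, int, str]                      # chain, seq_pos, element
    ligands: list[tuple[str, int, str, str, float]]  # chain, pos, res, atom, dist
    extended_shell: list[tuple[str, int, str, str, float]]
    metal_metal: dict[tuple[str, int], float]
    min_cu_cu_respected: bool


def _metal_atoms(structure: Structure) -> list[tuple[Residue, Atom]]:
    return [
        (res, atom)
        for res, atom in structure.atoms()
        if atom.element.upper() in METAL_NAMES and atom.is_hetero
    ]


def place_metal(
    structure: Structure,
    spec: MetalSiteSpec,
    chain_id: str | None = None,
    het_chain: str = "M",
) -> Structure:
    """Insert a metal (and its waters) at the least-squares coordination point.

    The metal position minimizes sum_i (|p - x_i| - t_i)^2 over the ligand
    atoms x_i with target distances t_i, solved numerically.  A single
    ligand forces the distance exactly, along the direction pointing away
    from the ligand's residue centroid (documented convention; the global
    +z axis breaks ties for a degenerate centroid).  Waters are placed at
    their target distance in the most sterically free directions.
    """
    if chain_id is None:
        chain_id = structure.chain_ids[0]
    if len(spec.ligands) < 1:
        raise ValueError("metal site needs at least one ligand")
    pts = []
    targets = []
    for pos, atom_name, dist in spec.ligands:
        res = structure.residue(chain_id, pos)
        pts.append(res.atom(atom_name).coords)
        targets.append(dist)
    pts = np.array(pts)
    targets = np.array(targets)

    if len(pts) == 1:
        res = structure.residue(chain_id, spec.ligands[0][0])
        centroid = np.mean([a.coords for a in res.atoms], axis=0)
        direction = pts[0] - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        metal_pos = pts[0] + targets[0] * direction
    else:
        def residuals(p: np.ndarray) -> np.ndarray:
            return np.linalg.norm(pts - p, axis=1) - targets

        best = None
        x0s = [pts.mean(axis=0)]
        # centroid is often near-degenerate (equidistant); offset starts
        for k, offset in enumerate(
            [np.array([1.5, 0, 0]), np.array([0, 1.5, 0]), np.array([0, 0, 1.5]),
             np.array([-1.5, 0, 0]), np.array([0, -1.5, 0]), np.array([0, 0, -1.5])]
        ):
            x0s.append(pts.mean(axis=0) + offset)
        for x0 in x0s:
            sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        metal_pos = best.x

    out = structure.copy()
    element = spec.element.upper()
    existing = [r.seq_pos for r in out.residues(het_chain)]
    next_pos = (max(existing) + 1) if existing else 1
    metal_res = Residue(
        het_chain, next_pos, element,
        [Atom(element, metal_pos, element, is_hetero=True)],
    )
    out.add_residue(metal_res)

    if spec.water_count:
        occupied = out.atom_coords()
        # deterministic Fibonacci directions, pick the most clearance
        n_dir = 64
        idx = np.arange(n_dir)
        golden = (1 + 5**0.5) / 2
        theta = 2 * np.pi * idx / golden
        z = 1 - 2 * (idx + 0.5) / n_dir
        r = np.sqrt(1 - z**2)
        dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        placed = 0
        scored = []
        for d in dirs:
            p = metal_pos + spec.water_distance * d
            clearance = float(np.min(np.linalg.norm(occupied - p, axis=1)))
            scored.append((clearance, tuple(p)))
        scored.sort(reverse=True)
        water_positions = []
        for clearance, p in scored:
            p = np.array(p)
            if any(np.linalg.norm(p - q) < 2.4 for q in water_positions):
                continue
            next_pos += 1
            out.add_residue(
                Residue(het_chain, next_pos, "HOH",
                        [Atom("O", p, "O", is_hetero=True)])
            )
            water_positions.append(p)
            placed += 1
            if placed == spec.water_count:
                break
    return out


def analyze_metal_site(
    structure: Structure,
    metal: tuple[str, int] | None = None,
    params: AnalysisParams | None = None,
) -> list[MetalSiteReport]:
    """Coordination report for each metal (or the selected one).

    Ligands are N/O/S atoms within the first-shell cutoff; candidates out to
    the extended shell are listed as near misses.  The mononuclear-center
    flag is true when every metal-metal separation is at least min_cu_cu.
    """
    params = params or AnalysisParams()
    metals = _metal_atoms(structure)
    if metal is not None:
        metals = [
            (r, a) for r, a in metals
            if (r.chain_id, r.seq_pos) == tuple(metal)
        ]
    if not metals:
        raise ValueError("no metal atoms present")
    all_metals = _metal_atoms(structure)
    reports = []
    for res_m, atom_m in metals:
        ligands = []
        shell = []
        for res, atom in structure.atoms():
            if atom is atom_m or atom.element.upper() in METAL_NAMES:
                continue
            if atom.element.upper() not in ("N", "O", "S"):
                continue
            d = float(np.linalg.norm(atom.coords - atom_m.coords))
            entry = (res.chain_id, res.seq_pos, res.res_name, atom.name, d)
            if d <= params.metal_ligand_cutoff:
                ligands.append(entry)
            elif d <= params.extended_shell:
                shell.append(entry)
        ligands.sort(key=lambda e: e[-1])
        shell.sort(key=lambda e: e[-1])
        mm = {}
        for res_o, atom_o in all_metals:
            if atom_o is atom_m:
                continue
            mm[(res_o.chain_id, res_o.seq_pos)] = float(
                np.linalg.norm(atom_o.coords - atom_m.coords)
            )
        flag = all(d >= params.min_cu_cu for d in mm.values())
        reports.append(
            MetalSiteReport(
                metal=(res_m.chain_id, res_m.seq_pos, atom_m.element.upper()),
                ligands=ligands,
                extended_shell=shell,
                metal_metal=mm,
                min_cu_cu_respected=flag,
            )
        )
    return reports


# -- Ramachandran ----------------------------------------------------------

# Polygonal (phi, psi) regions, degrees.  Vertices are a coarse, documented
# approximation of the usual favored/allowed contours; the beta region is
# split to handle the psi wrap at +/-180.
_GENERAL_FAVORED = [
    [(-180, 85), (-45, 85), (-45, 180), (-180, 180)],       # beta / PPII
    [(-180, -160), (-45, -160), (-45, -180), (-180, -180)],  # beta, wrapped
    [(-160, -75), (-45, -75), (-45, -5), (-160, -5)],        # alpha
]
_GENERAL_ALLOWED = [
    [(-180, 60), (-30, 60), (-30, 180), (-180, 180)],
    [(-180, -150), (-30, -150), (-30, -180), (-180, -180)],
    [(-180, -100), (-30, -100), (-30, 25), (-180, 25)],
    [(30, -25), (100, -25), (100, 90), (30, 90)],            # left-handed helix
]
_GLY_EXTRA_FAVORED = [
    [(45, 85), (180, 85), (180, 180), (45, 180)],
    [(45, -160), (180, -160), (180, -180), (45, -180)],
    [(45, -35), (180, -35), (180, 100), (45, 100)],
]
_GLY_EXTRA_ALLOWED = [
    [(30, -180), (180, -180), (180, 180), (30, 180)],
]
_PRO_FAVORED = [
    [(-110, 85), (-40, 85), (-40, 180), (-110, 180)],
    [(-110, -160), (-40, -160), (-40, -180), (-110, -180)],
    [(-110, -75), (-40, -75), (-40, -5), (-110, -5)],
]
_PRO_ALLOWED = [
    [(-120, 50), (-30, 50), (-30, 180), (-120, 180)],
    [(-120, -150), (-30, -150), (-30, -180), (-120, -180)],
    [(-120, -100), (-30, -100), (-30, 25), (-120, 25)],
]


def _paths(polys: list[list[tuple[float, float]]]) -> list[_MplPath]:
    return [_MplPath(np.array(p, dtype=float)) for p in polys]

_REGIONS = {
    "general": (_paths(_GENERAL_FAVORED), _paths(_GENERAL_ALLOWED)),
    "GLY": (
        _paths(_GENERAL_FAVORED + _GLY_EXTRA_FAVORED),
        _paths(_GENERAL_ALLOWED + _GLY_EXTRA_ALLOWED),
    ),
    "PRO": (_paths(_PRO_FAVORED), _paths(_PRO_ALLOWED)),
}


def classify_rama(phi: float, psi: float, res_name: str = "ALA") -> str:
    """favored / allowed / outlier for one (phi, psi) pair."""
    kind = res_name.upper() if res_name.upper() in ("GLY", "PRO") else "general"
    favored, allowed = _REGIONS[kind]
    point = (phi, psi)
    for path in favored:
        if path.contains_point(point):
            return "favored"
    for path in allowed:
        if path.contains_point(point):
            return "allowed"
    return "outlier"


@dataclass
class RamaReport:
    per_residue: list[tuple[str, int, float, float, str]]  # chain,pos,phi,psi,class
    fractions: dict[str, float]
    loop_outlier_fraction: float  # share of outliers assigned to loops

    @property
    def allowed_fraction(self) -> float:
        """Favored + allowed, the headline model-quality number."""
        return self.fractions["favored"] + self.fractions["allowed"]


def ramachandran(structure: Structure) -> RamaReport:
    """Classify every non-terminal residue of every chain."""
    rows = []
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    outlier_loop = 0
    for chain_id in structure.chain_ids:
        residues = structure.polymer_residues(chain_id)
        if len(residues) < 3:
            continue
        torsions = extract_torsions(structure, chain_id)
        ss = assign_ss(structure, chain_id)
        for i, res in enumerate(residues):
            if np.isnan(torsions.phi[i]) or np.isnan(torsions.psi[i]):
                continue
            cls = classify_rama(torsions.phi[i], torsions.psi[i], res.res_name)
            counts[cls] += 1
            rows.append(
                (chain_id, res.seq_pos, float(torsions.phi[i]),
                 float(torsions.psi[i]), cls)
            )
            if cls == "outlier" and ss[i] == "L":
                outlier_loop += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    loop_frac = outlier_loop / counts["outlier"] if counts["outlier"] else 0.0
    return RamaReport(rows, fractions, loop_frac)


# -- hydrogen bonds --------------------------------------------------------

_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",),
    "GLN": ("NE2",), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}


def _donors_acceptors(res: Residue) -> tuple[list[Atom], list[Atom]]:
    name = res.res_name.upper()
    donors: list[Atom] = []
    acceptors: list[Atom] = []
    if name in WATER_NAMES:
        for a in res.atoms:
            if a.element == "O":
                donors.append(a)
                acceptors.append(a)
        return donors, acceptors
    if res.has_atom("N") and name != "PRO":
        donors.append(res.atom("N"))
    if res.has_atom("O"):
        acceptors.append(res.atom("O"))
    for atom_name in _SIDECHAIN_DONORS.get(name, ()):
        if res.has_atom(atom_name):
            donors.append(res.atom(atom_name))
    for atom_name in _SIDECHAIN_ACCEPTORS.get(name, ()):
        if res.has_atom(atom_name):
            acceptors.append(res.atom(atom_name))
    return donors, acceptors


def _antecedent(structure: Structure, res: Residue, donor: Atom) -> np.ndarray | None:
    """Nearest covalently bonded heavy atom of the donor (<= 2.0 A)."""
    best = None
    best_d = 2.0
    candidates = list(res.atoms)
    idx = None
    chain = structure.polymer_residues(res.chain_id)
    for i, r in enumerate(chain):
        if r is res:
            idx = i
            break
    if idx is not None and donor.name == "N" and idx > 0:
        candidates.append(chain[idx - 1].atom("C"))
    for other in candidates:
        if other is donor:
            continue
        d = float(np.linalg.norm(other.coords - donor.coords))
        if d < best_d:
            best_d = d
            best = other.coords
    return best


def hbonds(
    structure: Structure,
    params: AnalysisParams | None = None,
    between: tuple[set[str] | None, set[str] | None] = (None, None),
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float, float]]:
    """Heavy-atom hydrogen bonds: donor-acceptor <= 3.5 A, donor angle >= 120.

    The donor angle is measured at the donor heavy atom between its bonded
    antecedent and the acceptor (a proxy for the unplaced hydrogen).
    `between` optionally restricts donors to chains in the first set and
    acceptors to chains in the second set (applied symmetrically).
    """
    params = params or AnalysisParams()
    sel_a, sel_b = between
    donors = []
    acceptors = []
    for res, _ in {id(r): (r, None) for r, _ in structure.atoms()}.values():
        d, a = _donors_acceptors(res)
        donors.extend((res, atom) for atom in d)
        acceptors.extend((res, atom) for atom in a)
    out = []
    for dres, datom in donors:
        ante = _antecedent(structure, dres, datom)
        for ares, aatom in acceptors:
            if dres is ares:
                continue
            if sel_a is not None and sel_b is not None:
                pair_ok = (
                    (dres.chain_id in sel_a and ares.chain_id in sel_b)
                    or (dres.chain_id in sel_b and ares.chain_id in sel_a)
                )
                if not pair_ok:
                    continue
            d = float(np.linalg.norm(datom.coords - aatom.coords))
            if d > params.hbond_max_donor_acceptor:
                continue
            if ante is not None:
                v1 = ante - datom.coords
                v2 = aatom.coords - datom.coords
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                # antecedent-donor-acceptor near 180 means the (implicit)
                # hydrogen points at the acceptor
                if angle < params.hbond_min_angle:
                    continue
            else:
                angle = float("nan")
            out.append(
                (
                    (dres.chain_id, dres.seq_pos, datom.name),
                    (ares.chain_id, ares.seq_pos, aatom.name),
                    d,
                    angle,
                )
            )
    return out


# -- secondary structure ---------------------------------------------------

# Torsion windows (degrees): assignments need runs of >= 3 residues.
_H_BOX = ((-100.0, -30.0), (-80.0, -10.0))
_E_BOX = ((-170.0, -70.0), (90.0, 180.0))
_E_BOX_WRAP = ((-170.0, -70.0), (-180.0, -170.0))


def _in_box(phi: float, psi: float, box) -> bool:
    (p0, p1), (s0, s1) = box
    return p0 <= phi <= p1 and s0 <= psi <= s1


def assign_ss(structure: Structure, chain_id: str | None = None) -> str:
    """Torsion-window secondary structure: H / E / L per residue.

    Residues fall in the helix or strand window by (phi, psi); runs shorter
    than 3 are relabeled loop.  Termini (undefined phi or psi) are loop.
    """
    if chain_id is None:
        ids = structure.chain_ids
        if len(ids) != 1:
            raise ValueError("chain_id required for multi-chain structures")
        chain_id = ids[0]
    torsions = extract_torsions(structure, chain_id)
    n = len(torsions)
    raw = []
    for i in range(n):
        phi, psi = torsions.phi[i], torsions.psi[i]
        if np.isnan(phi) or np.isnan(psi):
            raw.append("L")
        elif _in_box(phi, psi, _H_BOX):
            raw.append("H")
        elif _in_box(phi, psi, _E_BOX) or _in_box(phi, psi, _E_BOX_WRAP):
            raw.append("E")
        else:
            raw.append("L")
    # suppress runs < 3
    out = list(raw)
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        if raw[i] in "HE" and j - i < 3:
            for k in range(i, j):
                out[k] = "L"
        i = j
    return "".join(out)


def ss_agreement(assigned: str, predicted: str) -> float:
    """Percent of positions with equal labels."""
    if len(assigned) != len(predicted):
        raise ValueError("secondary-structure strings differ in length")
    if not assigned:
        return 0.0
    same = sum(a == b for a, b in zip(assigned, predicted))
    return 100.0 * same / len(assigned)


# -- clashes ---------------------------------------------------------------

def clashes(
    structure: Structure, threshold: float = 2.4
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Non-bonded heavy-atom pairs closer than `threshold` (strict).

    Pairs within the same chain are ignored when sequence separation <= 2
    (bonded or near-bonded); interchain pairs always count.
    """
    entries = list(structure.atoms())
    if len(entries) < 2:
        return []
    coords = np.array([a.coords for _, a in entries])
    d = cdist(coords, coords)
    out = []
    for i in range(len(entries)):
        ri, ai = entries[i]
        for j in range(i + 1, len(entries)):
            rj, aj = entries[j]
            if d[i, j] >= threshold:
                continue
            if ri.chain_id == rj.chain_id and abs(ri.seq_pos - rj.seq_pos) <= 2:
                continue
            out.append(
                (
                    (ri.chain_id, ri.seq_pos, ai.name),
                    (rj.chain_id, rj.seq_pos, aj.name),
                    float(d[i, j]),
                )
            )
    return out
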