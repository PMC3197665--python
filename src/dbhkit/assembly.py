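"""Torsion-space backbone construction and constraint-guided assembly.

Backbones are built with ideal bond lengths and angles from per-residue
(phi, psi, omega) dihedrals, so a chain is fully determined by its sequence
and TorsionSet.  On top of that sit the assembly searches: a greedy
torsion-space search that closes linkers onto disulfide/strand-pair
constraints, and rigid-body searches that orient chains so interchain
disulfides form.  All searches are monotone-improving and deterministic for
a fixed seed.

Ideal geometry used throughout (lengths in Angstrom, angles in degrees):
N-CA 1.458, CA-C 1.525, C-N 1.329, C-O 1.231; N-CA-C 111.2, CA-C-N 116.2,
C-N-CA 121.7, CA-C-O 120.8.  Omega is held at 180 (trans) during searches;
only phi/psi vary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from ._templates import SIDECHAIN_TEMPLATES
from .constraints import ConstraintSet, DisulfideConstraint
from .seqstats import one_to_three
from .structure import Atom, Residue, Structure, rigid_transform

__all__ = [
    "TorsionSet",
    "RigidTransform",
    "AssemblyScore",
    "place_atom",
    "dihedral",
    "kabsch",
    "build_backbone",
    "extract_torsions",
    "graft_fragment",
    "linker_search",
    "assemble_dimer",
    "assemble_tetramer",
]

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

CLASH_THRESHOLD = 2.4   # A, heavy-atom pair
CLASH_WEIGHT = 10.0     # per clash in AssemblyScore.total


# -- geometric primitives --------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Position d with |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) = torsion.

    Angles in degrees.  This is the standard natural-extension (NeRF)
    internal-to-Cartesian step.
    """
    angle_r = math.radians(angle)
    torsion_r = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # a, b, c collinear: any perpendicular completes the frame
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle_r),
            bond * math.sin(angle_r) * math.cos(torsion_r),
            bond * math.sin(angle_r) * math.sin(torsion_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R@mobile + t ~ target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, tc - rot @ mc


# -- torsions --------------------------------------------------------------

@dataclass
class TorsionSet:
    """Per-residue backbone dihedrals in degrees; NaN where undefined.

    phi[i] needs residue i-1 (undefined at the N-terminus), psi[i] needs
    residue i+1 (undefined at the C-terminus) and omega[i] is the dihedral
    CA(i-1)-C(i-1)-N(i)-CA(i) (undefined at the N-terminus).
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi, psi, omega must have equal length")
        for arr in (self.phi, self.psi, self.omega):
            defined = arr[~np.isnan(arr)]
            if np.any(defined <= -180.0) or np.any(defined > 180.0):
                raise ValueError("torsions must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    def copy(self) -> "TorsionSet":
        return TorsionSet(self.phi.copy(), self.psi.copy(), self.omega.copy())

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0) -> "TorsionSet":
        t = cls(np.full(n, phi), np.full(n, psi), np.full(n, omega))
        t.phi[0] = np.nan
        t.psi[-1] = np.nan
        t.omega[0] = np.nan
        return t


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(rotvec).as_matrix(), np.asarray(translation))

    def apply(self, structure: Structure) -> Structure:
        return rigid_transform(structure, self.rotation, self.translation)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation


@dataclass
class AssemblyScore:
    """Objective value of an assembly: distance violations plus clashes.

    total = constraint_violation + 10.0 * clash_penalty.  The weights are a
    toolkit convention (the manual procedure this automates had no explicit
    objective); they are documented, not fitted.
    """

    constraint_violation: float  # sum of squared (realized - target), A^2
    clash_penalty: int           # heavy-atom pairs closer than 2.4 A
    achieved_distances: tuple[float, ...] = ()
    trace: tuple[float, ...] = ()

    @property
    def total(self) -> float:
        return self.constraint_violation + CLASH_WEIGHT * self.clash_penalty


# -- backbone construction -------------------------------------------------

def _build_sidechain(res: Residue, coords: dict[str, np.ndarray]) -> None:
    template = SIDECHAIN_TEMPLATES.get(res.res_name.upper())
    if template is None:
        return
    local = dict(coords)
    for name, a, b, c, bond, angle, torsion in template:
        pos = place_atom(local[a], local[b], local[c], bond, angle, torsion)
        local[name] = pos
        res.add_atom(Atom(name, pos))


def build_backbone(
    sequence: str,
    torsions: TorsionSet,
    chain_id: str = "A",
    start_pos: int = 1,
    sidechains: bool = False,
) -> Structure:
    """Build an ideal-geometry chain from sequence and backbone dihedrals.

    extract_torsions(build_backbone(seq, t)) reproduces t to well below
    1e-6 degrees.  With sidechains=True, idealized heavy-atom stubs are
    attached (Cys SG, His ND1/NE2, Met SD, ... for every residue type).
    """
    n = len(sequence)
    if n != len(torsions):
        raise ValueError(
            f"sequence length {n} does not match torsion set length {len(torsions)}"
        )
    if n == 0:
        return Structure()
    phi, psi, omega = torsions.phi, torsions.psi, torsions.omega

    ncoords = np.zeros((n, 3))
    cacoords = np.zeros((n, 3))
    ccoords = np.zeros((n, 3))
    ncoords[0] = (0.0, 0.0, 0.0)
    cacoords[0] = (BOND_N_CA, 0.0, 0.0)
    theta = math.radians(180.0 - ANGLE_N_CA_C)
    ccoords[0] = cacoords[0] + BOND_CA_C * np.array(
        [math.cos(theta), math.sin(theta), 0.0]
    )
    for i in range(n - 1):
        psi_i = psi[i] if not np.isnan(psi[i]) else 180.0
        omega_next = omega[i + 1] if not np.isnan(omega[i + 1]) else 180.0
        phi_next = phi[i + 1] if not np.isnan(phi[i + 1]) else 180.0
        ncoords[i + 1] = place_atom(
            ncoords[i], cacoords[i], ccoords[i], BOND_C_N, ANGLE_CA_C_N, psi_i
        )
        cacoords[i + 1] = place_atom(
            cacoords[i], ccoords[i], ncoords[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega_next
        )
        ccoords[i + 1] = place_atom(
            ccoords[i], ncoords[i + 1], cacoords[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next
        )

    structure = Structure()
    for i, letter in enumerate(sequence):
        res = Residue(chain_id, start_pos + i, one_to_three(letter), [])
        res.add_atom(Atom("N", ncoords[i]))
        res.add_atom(Atom("CA", cacoords[i]))
        res.add_atom(Atom("C", ccoords[i]))
        psi_i = psi[i] if not np.isnan(psi[i]) else 180.0
        o = place_atom(
            ncoords[i], cacoords[i], ccoords[i], BOND_C_O, ANGLE_CA_C_O,
            psi_i + 180.0,
        )
        res.add_atom(Atom("O", o))
        if sidechains:
            _build_sidechain(
                res, {"N": ncoords[i], "CA": cacoords[i], "C": ccoords[i]}
            )
        structure.add_residue(res)
    return structure


def extract_torsions(structure: Structure, chain_id: str | None = None) -> TorsionSet:
    """Backbone (phi, psi, omega) of one chain; NaN at the termini."""
    if chain_id is None:
        ids = structure.chain_ids
        if len(ids) != 1:
            raise ValueError("chain_id required for multi-chain structures")
        chain_id = ids[0]
    residues = structure.polymer_residues(chain_id)
    n = len(residues)
    for res in residues:
        for name in ("N", "CA", "C"):
            if not res.has_atom(name):
                raise ValueError(
                    f"missing backbone atom {name} in residue "
                    f"{res.res_name}{res.seq_pos}"
                )
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    get = lambda i, name: residues[i].atom(name).coords
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(get(i - 1, "C"), get(i, "N"), get(i, "CA"), get(i, "C"))
            omega[i] = dihedral(
                get(i - 1, "CA"), get(i - 1, "C"), get(i, "N"), get(i, "CA")
            )
        if i < n - 1:
            psi[i] = dihedral(get(i, "N"), get(i, "CA"), get(i, "C"), get(i + 1, "N"))
    return TorsionSet(phi, psi, omega)


def graft_fragment(
    target: Structure,
    fragment: Structure,
    seq_range: tuple[int, int],
    chain_id: str | None = None,
) -> Structure:
    """Replace the torsions of `seq_range` by the fragment's torsions.

    The chain is rebuilt with ideal geometry and superposed back onto the
    part of the target preceding the range (falling back to the part after
    it), so each side keeps its internal geometry as a rigid body.
    """
    if chain_id is None:
        ids = target.chain_ids
        if len(ids) != 1:
            raise ValueError("chain_id required for multi-chain structures")
        chain_id = ids[0]
    residues = target.polymer_residues(chain_id)
    pos_index = {r.seq_pos: i for i, r in enumerate(residues)}
    start, end = seq_range
    if start > end or start not in pos_index or end not in pos_index:
        raise ValueError(f"range {seq_range} not within target chain")
    frag_res = fragment.polymer_residues(fragment.chain_ids[0])
    if len(frag_res) != end - start + 1:
        raise ValueError(
            f"fragment length {len(frag_res)} does not match range length "
            f"{end - start + 1}"
        )
    torsions = extract_torsions(target, chain_id)
    frag_t = extract_torsions(fragment, fragment.chain_ids[0])
    i0 = pos_index[start]
    for k in range(len(frag_res)):
        i = i0 + k
        if not np.isnan(frag_t.phi[k]):
            torsions.phi[i] = frag_t.phi[k]
        if not np.isnan(frag_t.psi[k]):
            torsions.psi[i] = frag_t.psi[k]
        if not np.isnan(frag_t.omega[k]):
            torsions.omega[i] = frag_t.omega[k]
    has_sidechains = any(len(r.atoms) > 4 for r in residues)
    sequence = target.sequence(chain_id)
    rebuilt = build_backbone(
        sequence,
        torsions,
        chain_id=chain_id,
        start_pos=residues[0].seq_pos,
        sidechains=has_sidechains,
    )
    # anchor on the rigid side
    anchor = [r.seq_pos for r in residues if r.seq_pos < start]
    if not anchor:
        anchor = [r.seq_pos for r in residues if r.seq_pos > end]
    if anchor:
        names = ("N", "CA", "C")
        mobile = np.array(
            [rebuilt.residue(chain_id, p).atom(nm).coords for p in anchor for nm in names]
        )
        ref = np.array(
            [target.residue(chain_id, p).atom(nm).coords for p in anchor for nm in names]
        )
        rot, tr = kabsch(mobile, ref)
        rebuilt = rigid_transform(rebuilt, rot, tr)
    return rebuilt


# -- scoring helpers -------------------------------------------------------

def _clash_count(coords: np.ndarray, exclude: np.ndarray | None = None) -> int:
    """Pairs closer than CLASH_THRESHOLD; `exclude` masks bonded pairs."""
    if len(coords) < 2:
        return 0
    d = cdist(coords, coords)
    mask = np.triu(d < CLASH_THRESHOLD, k=1)
    if exclude is not None:
        mask &= ~exclude
    return int(mask.sum())


def _chain_clashes(
    structure: Structure,
    exclude_pairs: set[frozenset[tuple[str, int]]] | None = None,
) -> int:
    """Non-bonded heavy-atom clashes (sequence separation > 2 or interchain).

    Residue pairs in `exclude_pairs` (e.g. constrained disulfide partners,
    which are covalently bonded by design) are not counted.
    """
    entries = list(structure.atoms())
    if len(entries) < 2:
        return 0
    coords = np.array([a.coords for _, a in entries])
    chain_ids = np.array([ord(r.chain_id) for r, _ in entries])
    pos = np.array([r.seq_pos for r, _ in entries])
    d = cdist(coords, coords)
    close = np.triu(d < CLASH_THRESHOLD, k=1)
    same_chain = chain_ids[:, None] == chain_ids[None, :]
    near_seq = np.abs(pos[:, None] - pos[None, :]) <= 2
    bondedish = same_chain & near_seq
    mask = close & ~bondedish
    if exclude_pairs:
        idx = np.argwhere(mask)
        for i, j in idx:
            ri, rj = entries[i][0], entries[j][0]
            key = frozenset(((ri.chain_id, ri.seq_pos), (rj.chain_id, rj.seq_pos)))
            if key in exclude_pairs:
                mask[i, j] = False
    return int(mask.sum())


def _interchain_soft_clash(a_coords: np.ndarray, b_coords: np.ndarray) -> float:
    d = cdist(a_coords, b_coords)
    gap = np.clip(CLASH_THRESHOLD - d, 0.0, None)
    return float(np.sum(gap**2))


# -- linker search ---------------------------------------------------------

def _active_constraints(
    cs: ConstraintSet, linker: tuple[int, int]
) -> tuple[list[DisulfideConstraint], list[tuple[int, int, float]]]:
    start, end = linker

    def spans(i: int, j: int) -> bool:
        lo, hi = min(i, j), max(i, j)
        return (lo < start and hi > end) or (start <= lo <= end) or (start <= hi <= end)

    disulfides = [
        ss
        for ss in cs.disulfides
        if ss.scope == "intrachain" and spans(ss.pos_i, ss.pos_j)
    ]
    strand_pairs = []
    for sp in cs.strand_pairs:
        for i, j in sp.pairs():
            if spans(i, j):
                strand_pairs.append((i, j, sp.target_ca_ca))
    return disulfides, strand_pairs


def linker_search(
    structure: Structure,
    linker_range: tuple[int, int],
    cs: ConstraintSet,
    iters: int = 1500,
    seed: int = 0,
    stop_tol: float = 0.04,
    restarts: int = 1,
) -> tuple[Structure, AssemblyScore]:
    """Torsion-space search over linker (phi, psi) onto spanning constraints.

    Moves are exact pivot rotations: perturbing phi rotates everything
    downstream of the N-CA bond, perturbing psi everything downstream of
    CA-C, so ideal internal geometry is preserved exactly and only the one
    dihedral changes.  Omega stays trans.  The walk is simulated annealing
    (geometric cooling with the temperature scaled to the current objective,
    followed by a greedy polish phase), run `restarts` times from the input
    conformation with independent streams; the returned structure and score
    trace track the best state visited, so the trace is monotone
    non-increasing.  The search stops early once the objective drops to
    `stop_tol` (A^2).  Residues before the linker never move.
    """
    chain_id = structure.chain_ids[0]
    residues = structure.polymer_residues(chain_id)
    pos_set = {r.seq_pos for r in residues}
    start, end = linker_range
    if start > end or start not in pos_set or end not in pos_set:
        raise ValueError(f"linker range {linker_range} not within chain")
    disulfides, strand_pairs = _active_constraints(cs, linker_range)
    if not disulfides and not strand_pairs:
        raise ValueError("unconstrained search: no active constraint spans the linker")

    # flatten to a coordinate array
    entries: list[tuple[int, str]] = []       # (residue index, atom name)
    coords_list: list[np.ndarray] = []
    res_atoms: list[dict[str, int]] = []
    for ri, res in enumerate(residues):
        table = {}
        for atom in res.atoms:
            table[atom.name] = len(entries)
            entries.append((ri, atom.name))
            coords_list.append(atom.coords.copy())
        res_atoms.append(table)
    coords = np.array(coords_list)
    n_atoms = len(coords)
    pos_of = [r.seq_pos for r in residues]
    index_of_pos = {p: i for i, p in enumerate(pos_of)}

    for ss in disulfides:
        for p in (ss.pos_i, ss.pos_j):
            if "SG" not in res_atoms[index_of_pos[p]]:
                raise ValueError(f"missing SG atom for disulfide {ss.pos_i}-{ss.pos_j}")
    ss_pairs = [
        (res_atoms[index_of_pos[ss.pos_i]]["SG"],
         res_atoms[index_of_pos[ss.pos_j]]["SG"],
         cs.params.ss_bond_target)
        for ss in disulfides
    ]
    ca_pairs = [
        (res_atoms[index_of_pos[i]]["CA"], res_atoms[index_of_pos[j]]["CA"], t)
        for i, j, t in strand_pairs
    ]

    # clash mask: sequence separation > 2, minus bonded-by-design pairs
    res_idx = np.array([ri for ri, _ in entries])
    pos_arr = np.array([pos_of[ri] for ri, _ in entries])
    consider = np.triu(np.abs(pos_arr[:, None] - pos_arr[None, :]) > 2, k=1)
    for ss in disulfides:
        ia = res_idx == index_of_pos[ss.pos_i]
        ib = res_idx == index_of_pos[ss.pos_j]
        consider &= ~(ia[:, None] & ib[None, :])
        consider &= ~(ib[:, None] & ia[None, :])

    def evaluate(xyz: np.ndarray) -> tuple[float, AssemblyScore]:
        violation = 0.0
        achieved = []
        for ia, ib, target in ss_pairs + ca_pairs:
            d = float(np.linalg.norm(xyz[ia] - xyz[ib]))
            achieved.append(d)
            violation += (d - target) ** 2
        dmat = cdist(xyz, xyz)
        n_clash = int((consider & (dmat < CLASH_THRESHOLD)).sum())
        score = AssemblyScore(violation, n_clash, tuple(achieved))
        return score.total, score

    # pivot index sets per linker residue
    linker_res = [index_of_pos[p] for p in range(start, end + 1) if p in index_of_pos]
    moves: list[tuple[int, int, np.ndarray]] = []  # (res idx, 0=phi/1=psi, subset)
    for ri in linker_res:
        downstream = res_idx > ri
        table = res_atoms[ri]
        phi_set = downstream.copy()
        for name, idx in table.items():
            if name not in ("N", "CA"):
                phi_set[idx] = True
        if ri > 0:  # phi defined
            moves.append((ri, 0, np.where(phi_set)[0]))
        psi_set = downstream.copy()
        if "O" in table:
            psi_set[table["O"]] = True
        if ri < len(residues) - 1:  # psi defined
            moves.append((ri, 1, np.where(psi_set)[0]))

    from scipy.spatial.transform import Rotation

    start_total, best_score = evaluate(coords)
    best_total = start_total
    trace = [best_total]
    best = coords.copy()

    def pivot(xyz: np.ndarray, move, delta_deg: float) -> np.ndarray:
        ri, which, subset = move
        table = res_atoms[ri]
        if which == 0:
            origin = xyz[table["N"]]
            axis = xyz[table["CA"]] - origin
        else:
            origin = xyz[table["CA"]]
            axis = xyz[table["C"]] - origin
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * math.radians(delta_deg)).as_matrix()
        out = xyz.copy()
        out[subset] = (out[subset] - origin) @ rot.T + origin
        return out

    if best_total > stop_tol and moves:
        sigmas = np.linspace(40.0, 2.0, num=max(iters, 1))
        # relative-temperature geometric cooling
        t_rel = 0.15 * (1e-3 / 0.15) ** (
            np.arange(max(iters, 1)) / max(iters - 1, 1)
        )
        polish_deltas = [0.5, -0.5, 1.0, -1.0, 2.0, -2.0, 4.0, -4.0,
                         8.0, -8.0, 16.0, -16.0]
        for restart in range(max(restarts, 1)):
            rng = np.random.default_rng((seed, restart))
            current = coords.copy()
            cur_total = start_total
            cur_score = None
            done = False
            for it in range(iters):
                move = moves[int(rng.integers(len(moves)))]
                delta = float(rng.normal(0.0, sigmas[it]))
                candidate = pivot(current, move, delta)
                total, score = evaluate(candidate)
                d_total = total - cur_total
                temperature = t_rel[it] * max(cur_total, 1e-9)
                if d_total <= 0 or rng.random() < math.exp(-d_total / temperature):
                    current = candidate
                    cur_total, cur_score = total, score
                    if total < best_total:
                        best_total, best_score = total, score
                        best = candidate
                        trace.append(total)
                        if best_total <= stop_tol:
                            done = True
                            break
            # deterministic polish: per-torsion line search, strictly monotone
            sweeps = 0
            while not done and sweeps < 10:
                improved = False
                for move in moves:
                    for delta in polish_deltas:
                        candidate = pivot(current, move, delta)
                        total, score = evaluate(candidate)
                        if total < cur_total - 1e-12:
                            current = candidate
                            cur_total, cur_score = total, score
                            improved = True
                            if total < best_total:
                                best_total, best_score = total, score
                                best = candidate
                                trace.append(total)
                                if best_total <= stop_tol:
                                    done = True
                            break
                    if done:
                        break
                sweeps += 1
                if not improved:
                    break
            if done:
                break

    out = structure.copy()
    out_res = out.polymer_residues(chain_id)
    for (ri, name), xyz in zip(entries, best):
        out_res[ri].atom(name).coords = xyz.copy()
    best_score.trace = tuple(trace)
    return out, best_score


# -- rigid-body assembly ---------------------------------------------------

def _sg_coords(structure: Structure, chain_id: str, positions: list[int]) -> np.ndarray:
    coords = []
    for pos in positions:
        res = structure.residue(chain_id, pos)
        if not res.has_atom("SG"):
            raise ValueError(f"missing SG atom at {chain_id}{pos}")
        coords.append(res.atom("SG").coords)
    return np.array(coords)


def assemble_dimer(
    a: Structure,
    b: Structure,
    interchain: list[DisulfideConstraint],
    iters: int = 40,
    seed: int = 0,
    ss_target: float = 2.05,
) -> tuple[Structure, AssemblyScore]:
    """Rigid-body placement of b so the interchain disulfides form.

    Random restarts (Kabsch-seeded and random orientations) followed by
    local refinement of the 6-dof transform, minimizing
    sum (SG-SG - target)^2 plus a soft interchain clash penalty.
    """
    if not interchain:
        raise ValueError("at least one interchain disulfide constraint required")
    chain_a = a.chain_ids[0]
    chain_b_orig = b.chain_ids[0]
    chain_b = chain_b_orig
    if chain_b in a.chain_ids:
        taken = set(a.chain_ids)
        chain_b = next(c for c in "BCDEFGH" if c not in taken)
        b = b.renamed_chain(chain_b_orig, chain_b)

    pos_a = [ss.pos_i for ss in interchain]
    pos_b = [ss.pos_j for ss in interchain]
    sg_a = _sg_coords(a, chain_a, pos_a)
    b_sg0 = _sg_coords(b, chain_b, pos_b)
    entries_a = list(a.atoms())
    entries_b = list(b.atoms())
    coords_a = np.array([at.coords for _, at in entries_a])
    coords_b0 = np.array([at.coords for _, at in entries_b])
    # bonded-by-design residue pairs carry no steric penalty against each other
    bond_free = np.zeros((len(entries_a), len(entries_b)), dtype=bool)
    for pa, pb in zip(pos_a, pos_b):
        ia = np.array([r.seq_pos == pa for r, _ in entries_a])
        ib = np.array([r.seq_pos == pb for r, _ in entries_b])
        bond_free |= ia[:, None] & ib[None, :]
    center_a = coords_a.mean(axis=0)
    center_b0 = coords_b0.mean(axis=0)
    rng = np.random.default_rng(seed)

    from scipy.spatial.transform import Rotation

    def transform_points(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (pts - center_b0) @ rot.T + center_b0 + params[3:]

    def objective(params: np.ndarray) -> float:
        sg_b = transform_points(params, b_sg0)
        d = np.linalg.norm(sg_a - sg_b, axis=1)
        f = float(np.sum((d - ss_target) ** 2))
        all_b = transform_points(params, coords_b0)
        gap = np.clip(CLASH_THRESHOLD - cdist(coords_a, all_b), 0.0, None)
        gap[bond_free] = 0.0
        return f + float(np.sum(gap**2))

    best_params = None
    best_val = np.inf
    # Kabsch seed: map b's constrained SGs onto points just outside a's SGs
    outward = sg_a - center_a
    norms = np.linalg.norm(outward, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    targets = sg_a + ss_target * outward / norms
    rot0, tr0 = kabsch(b_sg0, targets)
    seed_params = np.concatenate(
        [
            Rotation.from_matrix(rot0).as_rotvec(),
            rot0 @ center_b0 + tr0 - center_b0,
        ]
    )
    inits = [seed_params]
    for _ in range(max(iters - 1, 0)):
        rv = Rotation.random(random_state=rng).as_rotvec()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = center_a + direction * 1.2 * (
            np.ptp(coords_a, axis=0).max() / 2 + 4.0
        ) - center_b0
        inits.append(np.concatenate([rv, shift]))
    for x0 in inits:
        res = minimize(objective, x0, method="Powell",
                       options={"maxiter": 4000, "xtol": 1e-6, "ftol": 1e-10})
        if res.fun < best_val:
            best_val = float(res.fun)
            best_params = res.x
            if best_val < 1e-10:
                break

    rot = Rotation.from_rotvec(best_params[:3]).as_matrix()
    tr = best_params[3:] + center_b0 - rot @ center_b0
    placed_b = rigid_transform(b, rot, tr)
    merged = a.merged(placed_b)
    sg_b = _sg_coords(merged, chain_b, pos_b)
    achieved = tuple(float(x) for x in np.linalg.norm(sg_a - sg_b, axis=1))
    violation = float(np.sum((np.array(achieved) - ss_target) ** 2))
    bonded = {
        frozenset(((chain_a, pa), (chain_b, pb))) for pa, pb in zip(pos_a, pos_b)
    }
    clashes = _chain_clashes(merged, bonded)
    score = AssemblyScore(violation, clashes, achieved)
    return merged, score


def assemble_tetramer(
    dimer1: Structure,
    dimer2: Structure,
    hint_contacts: list[tuple[str, int, str, str, int, str]] | None = None,
    iters: int = 30,
    seed: int = 0,
    hint_target: float = 4.0,
) -> tuple[Structure, AssemblyScore]:
    """Rigid placement of dimer2 against dimer1 (non-covalent association).

    Hint contacts are (chain1, pos1, atom1, chain2, pos2, atom2) pairs pulled
    to <= hint_target Angstrom; with no hints any clash-free placement is
    accepted.  Chains of the two dimers must be disjoint.
    """
    shared = set(dimer1.chain_ids) & set(dimer2.chain_ids)
    if shared:
        raise ValueError(f"chain id collision: {sorted(shared)}")
    hint_contacts = hint_contacts or []
    coords_1 = dimer1.atom_coords()
    coords_2 = dimer2.atom_coords()
    center_2 = coords_2.mean(axis=0)
    pts_1 = []
    pts_2 = []
    for c1, p1, a1, c2, p2, a2 in hint_contacts:
        pts_1.append(dimer1.residue(c1, p1).atom(a1).coords)
        pts_2.append(dimer2.residue(c2, p2).atom(a2).coords)
    pts_1 = np.array(pts_1) if pts_1 else np.empty((0, 3))
    pts_2 = np.array(pts_2) if pts_2 else np.empty((0, 3))
    rng = np.random.default_rng(seed)

    from scipy.spatial.transform import Rotation

    def transform_points(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (pts - center_2) @ rot.T + center_2 + params[3:]

    def objective(params: np.ndarray) -> float:
        f = 0.0
        if len(pts_2):
            d = np.linalg.norm(pts_1 - transform_points(params, pts_2), axis=1)
            f += float(np.sum(np.clip(d - hint_target, 0.0, None) ** 2))
        f += _interchain_soft_clash(coords_1, transform_points(params, coords_2))
        return f

    extent = np.ptp(np.vstack([coords_1, coords_2]), axis=0).max() + 6.0
    best_params = None
    best_val = np.inf
    for k in range(max(iters, 1)):
        if k == 0 and len(pts_2):
            rv = np.zeros(3)
            shift = pts_1.mean(axis=0) - pts_2.mean(axis=0)
        else:
            rv = Rotation.random(random_state=rng).as_rotvec()
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = coords_1.mean(axis=0) + direction * extent - center_2
        res = minimize(objective, np.concatenate([rv, shift]), method="Powell",
                       options={"maxiter": 3000, "xtol": 1e-6, "ftol": 1e-10})
        if res.fun < best_val:
            best_val = float(res.fun)
            best_params = res.x
            if best_val < 1e-10:
                break

    rot = Rotation.from_rotvec(best_params[:3]).as_matrix()
    tr = best_params[3:] + center_2 - rot @ center_2
    merged = dimer1.merged(rigid_transform(dimer2, rot, tr))
    achieved = []
    violation = 0.0
    for c1, p1, a1, c2, p2, a2 in hint_contacts:
        d = float(
            np.linalg.norm(
                merged.residue(c1, p1).atom(a1).coords
                - merged.residue(c2, p2).atom(a2).coords
            )
        )
        achieved.append(d)
        violation += max(0.0, d - hint_target) ** 2
    score = AssemblyScore(violation, _chain_clashes(merged), tuple(achieved))
    return merged, score
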