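"""Seeded generators for every fixture class the pipeline needs.

These stand in for undeposited model coordinates: chains with prescribed
torsions, metal sites with ligand atoms at exact distances, oligomers with
planted interchain contacts at prescribed separations, and sequences/MSAs
with prescribed composition and conservation.  Every planted quantity is
recoverable by the corresponding analysis operation (distances to 1e-6 A,
counts exactly), and every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ._templates import SIDECHAIN_TEMPLATES
from .assembly import TorsionSet, build_backbone, place_atom
from .constraints import MetalSiteSpec
from .seqstats import one_to_three
from .structure import Atom, Residue, Structure, rigid_transform

__all__ = [
    "gen_chain",
    "gen_metal_site",
    "gen_two_metal_sites",
    "gen_dimer",
    "gen_oligomer",
    "gen_tetramer",
    "gen_msa",
    "gen_sequence",
    "make_residue",
    "place_residue_pair",
]

# Loop torsion library: (phi, psi) picks inside the allowed Ramachandran
# area but outside the helix/strand assignment windows (margin > noise).
_LOOP_LIBRARY = [(-90.0, 0.0), (60.0, 45.0), (-140.0, 70.0), (-55.0, 140.0),
                 (-80.0, -160.0)]
_SS_TORSIONS = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}


def gen_chain(
    sequence: str,
    ss_string: str | None = None,
    seed: int = 0,
    chain_id: str = "A",
    start_pos: int = 1,
) -> Structure:
    """Ideal-geometry chain with torsions drawn per secondary-structure class.

    H: (phi, psi) near (-57, -47); E: near (-120, +120); L: sampled from an
    allowed-region loop library.  Omega is trans.  Side-chain stubs (Cys SG,
    His ND1/NE2, Met SD, ...) are present for every residue.
    """
    if ss_string is None:
        ss_string = "L" * len(sequence)
    if len(sequence) != len(ss_string):
        raise ValueError(
            f"sequence length {len(sequence)} != ss string length {len(ss_string)}"
        )
    bad = set(ss_string) - set("HEL")
    if bad:
        raise ValueError(f"ss letters outside H/E/L: {bad}")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    for i, ss in enumerate(ss_string):
        if ss in _SS_TORSIONS:
            p0, s0 = _SS_TORSIONS[ss]
            phi_i = p0 + rng.uniform(-8.0, 8.0)
            psi_i = s0 + rng.uniform(-8.0, 8.0)
        else:
            p0, s0 = _LOOP_LIBRARY[int(rng.integers(len(_LOOP_LIBRARY)))]
            phi_i = p0 + rng.uniform(-6.0, 6.0)
            psi_i = s0 + rng.uniform(-6.0, 6.0)
        phi[i] = phi_i
        psi[i] = min(psi_i, 180.0)
        omega[i] = 180.0
    phi[0] = np.nan
    psi[-1] = np.nan
    omega[0] = np.nan
    torsions = TorsionSet(phi, psi, omega)
    return build_backbone(sequence, torsions, chain_id, start_pos, sidechains=True)


# -- isolated residues -----------------------------------------------------

def make_residue(
    res3: str,
    chain_id: str = "A",
    seq_pos: int = 1,
    origin: np.ndarray | None = None,
) -> Residue:
    """One idealized residue (backbone + template side chain) at `origin`."""
    res3 = res3.upper()
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    theta = np.radians(180.0 - 111.2)
    c = ca + 1.525 * np.array([np.cos(theta), np.sin(theta), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.8, 0.0)
    res = Residue(chain_id, seq_pos, res3, [])
    res.add_atom(Atom("N", n))
    res.add_atom(Atom("CA", ca))
    res.add_atom(Atom("C", c))
    res.add_atom(Atom("O", o))
    local = {"N": n, "CA": ca, "C": c}
    for name, a, b, cc, bond, angle, torsion in SIDECHAIN_TEMPLATES[res3]:
        pos = place_atom(local[a], local[b], local[cc], bond, angle, torsion)
        local[name] = pos
        res.add_atom(Atom(name, pos))
    if origin is not None:
        shift = np.asarray(origin, dtype=float) - res.atom("CA").coords
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    return res


def _orient_residue(res: Residue, anchor_atom: str, direction: np.ndarray) -> None:
    """Rotate/translate so the residue body extends from its anchor atom
    along `direction`, with the anchor atom at the origin."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    centroid = np.mean([a.coords for a in res.atoms], axis=0)
    v = centroid - res.atom(anchor_atom).coords
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        rot = np.eye(3)
    else:
        rot, _ = Rotation.align_vectors(direction[None, :], (v / norm)[None, :])
        rot = rot.as_matrix()
    anchor = res.atom(anchor_atom).coords.copy()
    for atom in res.atoms:
        atom.coords = rot @ (atom.coords - anchor)


def place_residue_pair(
    res3_a: str,
    atom_a: str,
    res3_b: str,
    atom_b: str,
    distance: float,
    chain_a: str = "A",
    chain_b: str = "B",
    pos_a: int = 1,
    pos_b: int = 1,
) -> Structure:
    """Two isolated residues with the named atoms at exactly `distance` A.

    The residues point away from each other along the contact axis, so the
    named atom pair realises the minimum interatomic distance.
    """
    ra = make_residue(res3_a, chain_a, pos_a)
    rb = make_residue(res3_b, chain_b, pos_b)
    _orient_residue(ra, atom_a, np.array([-1.0, 0.0, 0.0]))
    _orient_residue(rb, atom_b, np.array([1.0, 0.0, 0.0]))
    for atom in rb.atoms:
        atom.coords = atom.coords + np.array([distance, 0.0, 0.0])
    s = Structure()
    s.add_residue(ra)
    s.add_residue(rb)
    return s


# -- metal sites -----------------------------------------------------------

# Deterministic spherical codes: unit directions with non-degenerate spread.
_SQ3 = 1.0 / np.sqrt(3.0)
_DIRECTION_CODES = {
    1: [(0, 0, 1)],
    2: [(0, 0, 1), (1, 0, 0)],
    3: [(1, 0, 0), (-0.5, np.sqrt(3) / 2, 0), (-0.5, -np.sqrt(3) / 2, 0)],
    4: [(_SQ3, _SQ3, _SQ3), (_SQ3, -_SQ3, -_SQ3), (-_SQ3, _SQ3, -_SQ3),
        (-_SQ3, -_SQ3, _SQ3)],
    5: [(1, 0, 0), (-0.5, np.sqrt(3) / 2, 0), (-0.5, -np.sqrt(3) / 2, 0),
        (0, 0, 1), (0, 0, -1)],
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}

_ATOM_HOST = {
    "ND1": "HIS", "NE2": "HIS", "SG": "CYS", "SD": "MET", "OG": "SER",
    "OE1": "GLU", "OE2": "GLU", "OD1": "ASP", "OD2": "ASP", "NZ": "LYS",
    "NH1": "ARG", "NH2": "ARG", "NE": "ARG", "OH": "TYR", "OG1": "THR",
    "CD1": "LEU", "CD2": "LEU",
}


def gen_metal_site(
    spec: MetalSiteSpec,
    seed: int = 0,
    chain_id: str = "A",
    het_chain: str = "M",
    origin: np.ndarray | None = None,
) -> Structure:
    """Metal at the origin with ligand atoms at exactly the requested distances.

    Ligand directions come from deterministic spherical codes, so distances
    are exact by construction; host residues are built rigidly around each
    ligand atom, pointing away from the metal.
    """
    n_points = len(spec.ligands) + spec.water_count
    if not 1 <= len(spec.ligands) <= 6 or n_points > 6:
        raise ValueError("1-6 ligand directions supported")
    dirs = np.array(_DIRECTION_CODES[n_points], dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    s = Structure()
    placed_coords: list[np.ndarray] = []
    for k, (pos, atom_name, dist) in enumerate(spec.ligands):
        host = _ATOM_HOST.get(atom_name.upper())
        if host is None:
            raise ValueError(f"no host residue template for atom {atom_name!r}")
        res = make_residue(host, chain_id, pos)
        _orient_residue(res, atom_name, dirs[k])
        target = origin + dist * dirs[k]
        base = np.array([a.coords for a in res.atoms])
        # spin about the ligand axis to maximize clearance from other hosts
        best_coords, best_clear = None, -np.inf
        for spin in range(12):
            rot = Rotation.from_rotvec(np.radians(30.0 * spin) * dirs[k]).as_matrix()
            coords = base @ rot.T + target
            clear = (
                min(cdist(coords, prev).min() for prev in placed_coords)
                if placed_coords
                else np.inf
            )
            if clear > best_clear:
                best_clear, best_coords = clear, coords
            if clear == np.inf:
                break
        if placed_coords and best_clear < 1.0:
            raise ValueError("infeasible metal-site spec: overlapping ligands")
        for atom, coords in zip(res.atoms, best_coords):
            atom.coords = coords
        placed_coords.append(best_coords)
        s.add_residue(res)
    metal = Residue(
        het_chain, 1, spec.element.upper(),
        [Atom(spec.element.upper(), origin.copy(), spec.element.upper(),
              is_hetero=True)],
    )
    s.add_residue(metal)
    for w in range(spec.water_count):
        direction = dirs[len(spec.ligands) + w]
        s.add_residue(
            Residue(het_chain, 2 + w, "HOH",
                    [Atom("O", origin + spec.water_distance * direction, "O",
                          is_hetero=True)])
        )
    return s


def gen_two_metal_sites(
    spec_a: MetalSiteSpec,
    spec_b: MetalSiteSpec,
    separation: float,
    seed: int = 0,
) -> Structure:
    """Two metal sites with the metal-metal distance exactly `separation` A."""
    site_a = gen_metal_site(spec_a, seed, chain_id="A", het_chain="M")
    offset = np.array([separation, 0.0, 0.0])
    site_b = gen_metal_site(spec_b, seed, chain_id="B", het_chain="N",
                            origin=offset)
    # rotate site B so its ligands point away from site A
    rot = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    site_b = rigid_transform(site_b, rot, offset - rot @ offset)
    return site_a.merged(site_b)


# -- oligomers with planted contacts --------------------------------------

def _infer_sequence(contacts_for_chain: list[tuple[int, str]], length: int) -> str:
    seq = ["A"] * length
    for pos, atom in contacts_for_chain:
        host = _ATOM_HOST.get(atom.upper())
        if host is None and atom.upper() in ("N", "CA", "CB", "C", "O"):
            host = "ALA"
        if host is None:
            raise ValueError(f"cannot infer residue type for atom {atom!r}")
        from .seqstats import three_to_one

        seq[pos - 1] = three_to_one(host)
    return "".join(seq)


def gen_oligomer(
    contacts: list[tuple[str, int, str, str, int, str, float]],
    seed: int = 0,
    chain_length: int | None = None,
    sequences: dict[str, str] | None = None,
    clearance: float = 4.5,
    tol: float = 0.01,
    max_restarts: int = 24,
) -> Structure:
    """Chains positioned so each planted atom pair sits at its separation.

    Contacts are (chain_i, pos_i, atom_i, chain_j, pos_j, atom_j, distance).
    Chains are extended idealized backbones (sequence inferred from the
    contact atoms unless given).  Each chain after the first is rigidly
    placed by bounded optimization: planted distances within `tol`, and
    residue pairs not involved in any planted contact kept at least
    `clearance` apart.  Raises if the spec cannot be satisfied.
    """
    chain_ids = sorted(
        {c[0] for c in contacts} | {c[3] for c in contacts}
    )
    if sequences is None:
        sequences = {}
        for cid in chain_ids:
            involved = [
                (p, a) for (ci, p, a, cj, q, b, d) in contacts if ci == cid
            ] + [
                (q, b) for (ci, p, a, cj, q, b, d) in contacts if cj == cid
            ]
            length = chain_length or (max(p for p, _ in involved) + 2)
            sequences[cid] = _infer_sequence(involved, length)
    rng = np.random.default_rng(seed)
    placed: dict[str, Structure] = {}
    result: Structure | None = None
    contact_residues: dict[str, set[int]] = {cid: set() for cid in chain_ids}
    for ci, p, a, cj, q, b, d in contacts:
        contact_residues[ci].add(p)
        contact_residues[cj].add(q)

    for n_chain, cid in enumerate(chain_ids):
        # extended conformation: rod-like, clash-free chains
        chain = build_backbone(
            sequences[cid], TorsionSet.uniform(len(sequences[cid]), 180.0, 180.0),
            chain_id=cid, sidechains=True,
        )
        if result is None:
            placed[cid] = chain
            result = chain
            continue
        active = [
            (ci, p, a, cj, q, b, d)
            for (ci, p, a, cj, q, b, d) in contacts
            if (cj == cid and ci in placed) or (ci == cid and cj in placed)
        ]
        if not active:
            # park the chain far from everything
            span = np.ptp(result.atom_coords(), axis=0).max() + 30.0
            chain = rigid_transform(chain, np.eye(3),
                                    np.array([0.0, span * n_chain, 0.0]))
            placed[cid] = chain
            result = result.merged(chain)
            continue

        fixed_pts = []
        mobile_pts = []
        targets = []
        for ci, p, a, cj, q, b, d in active:
            if cj == cid:
                fixed_pts.append(result.residue(ci, p).atom(a).coords)
                mobile_pts.append(chain.residue(cid, q).atom(b).coords)
            else:
                fixed_pts.append(result.residue(cj, q).atom(b).coords)
                mobile_pts.append(chain.residue(cid, p).atom(a).coords)
            targets.append(d)
        fixed_pts = np.array(fixed_pts)
        mobile_pts = np.array(mobile_pts)
        targets = np.array(targets)

        fixed_entries = [
            (r.chain_id, r.seq_pos, at.coords) for r, at in result.atoms()
        ]
        fixed_coords = np.array([e[2] for e in fixed_entries])
        fixed_free = np.array(
            [r_pos not in contact_residues.get(r_cid, set())
             for r_cid, r_pos, _ in fixed_entries]
        )
        mobile_entries = [(r.seq_pos, at.coords) for r, at in chain.atoms()]
        mobile_coords0 = np.array([e[1] for e in mobile_entries])
        mobile_free = np.array(
            [pos not in contact_residues[cid] for pos, _ in mobile_entries]
        )
        center = mobile_coords0.mean(axis=0)
        # pairs where either residue is planted only need to avoid overlap
        pair_clearance = np.where(
            fixed_free[:, None] & mobile_free[None, :], clearance, 2.0
        )

        def transform(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            return (pts - center) @ rot.T + center + params[3:]

        def objective(params: np.ndarray) -> float:
            dd = np.linalg.norm(fixed_pts - transform(params, mobile_pts), axis=1)
            f = float(np.sum((dd - targets) ** 2))
            allm = transform(params, mobile_coords0)
            gap = np.clip(pair_clearance - cdist(fixed_coords, allm), 0.0, None)
            return f + float(np.sum(gap**2))

        best = None
        for restart in range(max_restarts):
            rv = (np.zeros(3) if restart == 0
                  else Rotation.random(random_state=rng).as_rotvec())
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = (fixed_pts.mean(axis=0) + direction * (targets.mean() + 8.0)
                     - mobile_pts.mean(axis=0))
            res = minimize(objective, np.concatenate([rv, shift]), method="Powell",
                           options={"maxiter": 4000, "xtol": 1e-8, "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e-8:
                break
        moved = transform(best.x, mobile_coords0)
        dd = np.linalg.norm(fixed_pts - transform(best.x, mobile_pts), axis=1)
        if np.any(np.abs(dd - targets) > tol):
            raise ValueError(
                f"unsatisfiable contact spec for chain {cid}: "
                f"achieved {np.round(dd, 3).tolist()} vs targets {targets.tolist()}"
            )
        rot = Rotation.from_rotvec(best.x[:3]).as_matrix()
        tr = best.x[3:] + center - rot @ center
        chain = rigid_transform(chain, rot, tr)
        placed[cid] = chain
        result = result.merged(chain)
    return result


def gen_dimer(
    contact_spec: list[tuple[int, int, tuple[str, str], float]],
    seed: int = 0,
    chain_length: int | None = None,
    sequences: dict[str, str] | None = None,
) -> Structure:
    """Two chains (A, B) with planted contacts at prescribed separations.

    contact_spec rows are (resA, resB, (atomA, atomB), distance_A).
    """
    contacts = [
        ("A", pa, aa, "B", pb, ab, d) for pa, pb, (aa, ab), d in contact_spec
    ]
    return gen_oligomer(contacts, seed, chain_length, sequences)


def gen_tetramer(
    contacts: list[tuple[str, int, str, str, int, str, float]],
    seed: int = 0,
    chain_length: int | None = None,
    sequences: dict[str, str] | None = None,
) -> Structure:
    """Four chains (A-D) with planted interchain contacts."""
    ids = sorted({c[0] for c in contacts} | {c[3] for c in contacts})
    if not set(ids) <= {"A", "B", "C", "D"}:
        raise ValueError("tetramer chains must be A-D")
    if sequences is not None:
        missing = set("ABCD") - set(sequences)
        if missing:
            raise ValueError(f"sequences missing for chains {sorted(missing)}")
    out = gen_oligomer(contacts, seed, chain_length, sequences)
    # park any chain not referenced by a contact
    span = np.ptp(out.atom_coords(), axis=0).max() + 30.0
    k = 1
    for cid in "ABCD":
        if cid not in out.chain_ids:
            seq = (sequences or {}).get(cid, "A" * (chain_length or 8))
            chain = build_backbone(
                seq, TorsionSet.uniform(len(seq), 180.0, 180.0),
                chain_id=cid, sidechains=True,
            )
            chain = rigid_transform(
                chain, np.eye(3), np.array([0.0, 0.0, span * k])
            )
            out = out.merged(chain)
            k += 1
    return out


# -- sequences and alignments ---------------------------------------------

_NEUTRAL = "AGHILMNPQSTVWFY"


def gen_sequence(
    length: int,
    n_cys: int = 0,
    n_neg: int = 0,
    n_pos: int = 0,
    seed: int = 0,
) -> str:
    """Random sequence with exact Cys / (Asp+Glu) / (Arg+Lys) counts."""
    if n_cys + n_neg + n_pos > length:
        raise ValueError(
            f"composition counts ({n_cys}+{n_neg}+{n_pos}) exceed length {length}"
        )
    rng = np.random.default_rng(seed)
    letters = (
        ["C"] * n_cys
        + [str(rng.choice(list("DE"))) for _ in range(n_neg)]
        + [str(rng.choice(list("RK"))) for _ in range(n_pos)]
        + [str(rng.choice(list(_NEUTRAL)))
           for _ in range(length - n_cys - n_neg - n_pos)]
    )
    rng.shuffle(letters)
    return "".join(letters)


def gen_msa(
    n_seqs: int,
    n_cols: int,
    conserved_fraction: float,
    seed: int = 0,
) -> list[str]:
    """MSA with exactly round(conserved_fraction * n_cols) conserved columns."""
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in [0, 1]")
    n_conserved = round(conserved_fraction * n_cols)
    if n_seqs < 2 and n_conserved < n_cols:
        raise ValueError("need at least 2 sequences for non-conserved columns")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    conserved_cols = set(
        rng.choice(n_cols, size=n_conserved, replace=False).tolist()
    )
    columns = []
    for col in range(n_cols):
        if col in conserved_cols:
            letter = str(rng.choice(alphabet))
            columns.append([letter] * n_seqs)
        else:
            letters = [str(rng.choice(alphabet)) for _ in range(n_seqs)]
            if len(set(letters)) == 1:
                alt = str(rng.choice(alphabet[alphabet != letters[0]]))
                letters[-1] = alt
            columns.append(letters)
    return ["".join(columns[c][r] for c in range(n_cols)) for r in range(n_seqs)]
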