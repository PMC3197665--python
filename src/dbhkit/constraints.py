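"""Biochemical constraint sets that drive assembly and validation.

A ConstraintSet bundles everything the toolkit knows about a protein before
coordinates exist: expected disulfide bonds (intra- and interchain), metal
coordination targets from spectroscopy, a secondary-structure prediction
string, strand-pairing expectations, named domain ranges and the analysis
cutoffs.  `default_dbh_constraints` encodes the full prior for human
dopamine beta-hydroxylase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from ._templates import residue_heavy_atoms
from .seqstats import one_to_three

__all__ = [
    "DisulfideConstraint",
    "MetalSiteSpec",
    "StrandPairConstraint",
    "AnalysisParams",
    "ConstraintSet",
    "ConstraintError",
    "load_constraints",
    "save_constraints",
    "default_dbh_constraints",
    "count_disulfides",
    "DBH_DOMAIN_RANGES",
]


class ConstraintError(ValueError):
    """Raised when a constraint fails validation against its sequence."""


@dataclass(frozen=True)
class DisulfideConstraint:
    pos_i: int
    pos_j: int
    scope: str = "intrachain"  # intrachain | interchain
    soft: bool = False         # reported separately, never a hard failure
    chain_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("intrachain", "interchain"):
            raise ValueError(f"unknown disulfide scope {self.scope!r}")
        if self.scope == "intrachain" and self.pos_i == self.pos_j:
            raise ValueError("intrachain disulfide needs two distinct positions")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted({self.pos_i, self.pos_j}))


@dataclass(frozen=True)
class MetalSiteSpec:
    label: str  # CuA | CuB | user label
    ligands: tuple[tuple[int, str, float], ...]  # (residue pos, atom name, target A)
    water_count: int = 0
    water_distance: float = 1.94
    element: str = "CU"
    notes: str = ""

    def __post_init__(self) -> None:
        for pos, atom, dist in self.ligands:
            if dist <= 0:
                raise ValueError(f"ligand target distance must be > 0 ({pos} {atom})")
        if self.water_count and self.water_distance <= 0:
            raise ValueError("water target distance must be > 0")


@dataclass(frozen=True)
class StrandPairConstraint:
    range_a: tuple[int, int]
    range_b: tuple[int, int]
    target_ca_ca: float = 5.0

    def __post_init__(self) -> None:
        a0, a1 = self.range_a
        b0, b1 = self.range_b
        if a0 > a1 or b0 > b1:
            raise ValueError("strand ranges must be (start, end) with start <= end")
        if not (a1 < b0 or b1 < a0):
            raise ValueError("strand ranges must be disjoint")

    def pairs(self) -> list[tuple[int, int]]:
        """Antiparallel residue pairing: first of A with last of B, etc."""
        a = list(range(self.range_a[0], self.range_a[1] + 1))
        b = list(range(self.range_b[1], self.range_b[0] - 1, -1))
        return list(zip(a, b))


@dataclass(frozen=True)
class AnalysisParams:
    salt_bridge_cutoff: float = 7.0      # A, inclusive
    electrostatic_cutoff: float = 4.0    # A, strict <
    snp_radius: float = 6.0              # A, any-heavy-atom neighborhood
    metal_ligand_cutoff: float = 3.0     # A, first coordination shell
    extended_shell: float = 6.5          # A, near-miss candidate ligands
    ss_bond_target: float = 2.05         # A, SG-SG
    ss_bond_tolerance: float = 0.3       # A
    hbond_max_donor_acceptor: float = 3.5  # A, heavy-atom proxy
    hbond_min_angle: float = 120.0       # degrees at the donor heavy atom
    min_cu_cu: float = 7.0               # A, mononuclear-center lower bound
    probe_radius: float = 1.4            # A, solvent probe
    hydrophobic_cc_cutoff: float = 4.0   # A, side-chain carbon-carbon
    clash_threshold: float = 2.4         # A, non-bonded heavy-atom pairs
    surface_rel_exposure: float = 0.25   # relative SASA for surface flag
    active_site_metal_dist: float = 8.0  # A, active-site-proximal SNP rule

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.electrostatic_cutoff >= self.salt_bridge_cutoff:
            raise ValueError("electrostatic cutoff must be below salt-bridge cutoff")


DBH_DOMAIN_RANGES: dict[str, tuple[int, int]] = {
    "DOMON": (57, 173),
    "Cu_monooxygenase_N": (196, 344),
    "Cu_monooxygenase_C": (359, 526),
}


@dataclass
class ConstraintSet:
    sequence: str = ""
    disulfides: list[DisulfideConstraint] = field(default_factory=list)
    metal_sites: list[MetalSiteSpec] = field(default_factory=list)
    ss_prediction: str = ""
    strand_pairs: list[StrandPairConstraint] = field(default_factory=list)
    domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        n = len(self.sequence)
        if self.ss_prediction:
            bad = set(self.ss_prediction) - set("HEL")
            if bad:
                raise ConstraintError(f"ss_prediction letters outside H/E/L: {bad}")
            if n and len(self.ss_prediction) != n:
                raise ConstraintError("ss_prediction length differs from sequence")
        for ss in self.disulfides:
            for pos in {ss.pos_i, ss.pos_j}:
                self._check_pos(pos)
                if n and self.sequence[pos - 1].upper() != "C":
                    raise ConstraintError(
                        f"disulfide position {pos} is not cysteine "
                        f"({self.sequence[pos - 1].upper()})"
                    )
        for site in self.metal_sites:
            for pos, atom, _ in site.ligands:
                self._check_pos(pos)
                if n:
                    res3 = one_to_three(self.sequence[pos - 1])
                    if atom not in residue_heavy_atoms(res3):
                        raise ConstraintError(
                            f"metal site {site.label}: residue {res3}{pos} "
                            f"has no atom {atom!r}"
                        )
        for sp in self.strand_pairs:
            for pos in (*sp.range_a, *sp.range_b):
                self._check_pos(pos)
        ranges = sorted(self.domain_ranges.values())
        for (s0, e0), (s1, e1) in zip(ranges, ranges[1:]):
            if s1 <= e0:
                raise ConstraintError("domain ranges overlap")
        for name, (s, e) in self.domain_ranges.items():
            self._check_pos(s)
            self._check_pos(e)
            if s > e:
                raise ConstraintError(f"domain {name}: start after end")

    def _check_pos(self, pos: int) -> None:
        if pos < 1:
            raise ConstraintError(f"position {pos} out of range")
        if self.sequence and pos > len(self.sequence):
            raise ConstraintError(
                f"position {pos} beyond sequence length {len(self.sequence)}"
            )

    def domain_of(self, pos: int) -> str | None:
        for name, (start, end) in self.domain_ranges.items():
            if start <= pos <= end:
                return name
        return None


def count_disulfides(cs: ConstraintSet) -> tuple[int, int]:
    """(bonds contributed per subunit, distinct Cys positions engaged)."""
    intra = sum(1 for ss in cs.disulfides if ss.scope == "intrachain")
    inter = sum(1 for ss in cs.disulfides if ss.scope == "interchain")
    engaged: set[int] = set()
    for ss in cs.disulfides:
        engaged.update(ss.positions)
    return intra + inter, len(engaged)


def default_dbh_constraints(sequence: str) -> ConstraintSet:
    """The full biochemical prior for the 617-residue DBH precursor.

    Six intrachain disulfides (Cys390-Cys503 soft: tolerated as unformed,
    reported separately), interchain bonds at Cys528 and Cys530, the two
    EPR-derived Cu sites (CuA: 3 His ND1 at 1.99 A plus one water at 1.94 A;
    CuB: 2 His NE2 plus one water; Met487 SD noted as the reduced-state
    ligand, not placed), the DOMON/monooxygenase domain ranges and the
    50-53 / 193-197 strand pairing.
    """
    cs = ConstraintSet(
        sequence=sequence,
        disulfides=[
            DisulfideConstraint(154, 596),
            DisulfideConstraint(232, 283),
            DisulfideConstraint(269, 295),
            DisulfideConstraint(390, 503, soft=True),
            DisulfideConstraint(394, 565),
            DisulfideConstraint(466, 488),
            DisulfideConstraint(528, 528, scope="interchain"),
            DisulfideConstraint(530, 530, scope="interchain"),
        ],
        metal_sites=[
            MetalSiteSpec(
                label="CuA",
                ligands=((262, "ND1", 1.99), (263, "ND1", 1.99), (333, "ND1", 1.99)),
                water_count=1,
                water_distance=1.94,
            ),
            MetalSiteSpec(
                label="CuB",
                ligands=((412, "NE2", 1.99), (414, "NE2", 1.99)),
                water_count=1,
                water_distance=1.94,
                notes=(
                    "third ligand X unidentified (His or O-donor or solvent); "
                    "Met487 SD is the reduced-state ligand and is not placed"
                ),
            ),
        ],
        strand_pairs=[StrandPairConstraint((50, 53), (193, 197), target_ca_ca=5.0)],
        domain_ranges=dict(DBH_DOMAIN_RANGES),
    )
    cs.validate()
    return cs


# -- YAML round-trip -------------------------------------------------------

def _cs_to_dict(cs: ConstraintSet) -> dict:
    return {
        "sequence": cs.sequence,
        "disulfides": [
            {
                "pos_i": ss.pos_i,
                "pos_j": ss.pos_j,
                "scope": ss.scope,
                "soft": ss.soft,
                **(
                    {"chain_pair": list(ss.chain_pair)}
                    if ss.chain_pair is not None
                    else {}
                ),
            }
            for ss in cs.disulfides
        ],
        "metal_sites": [
            {
                "label": site.label,
                "element": site.element,
                "ligands": [
                    {"pos": pos, "atom": atom, "distance": dist}
                    for pos, atom, dist in site.ligands
                ],
                "water_ligands": {
                    "count": site.water_count,
                    "distance": site.water_distance,
                },
                "notes": site.notes,
            }
            for site in cs.metal_sites
        ],
        "ss_prediction": cs.ss_prediction,
        "strand_pairs": [
            {
                "range_a": list(sp.range_a),
                "range_b": list(sp.range_b),
                "target_ca_ca": sp.target_ca_ca,
            }
            for sp in cs.strand_pairs
        ],
        "domain_ranges": {k: list(v) for k, v in cs.domain_ranges.items()},
        "params": asdict(cs.params),
    }


def _cs_from_dict(data: dict) -> ConstraintSet:
    params = AnalysisParams(**data.get("params", {}))
    cs = ConstraintSet(
        sequence=data.get("sequence", "") or "",
        disulfides=[
            DisulfideConstraint(
                d["pos_i"],
                d["pos_j"],
                d.get("scope", "intrachain"),
                d.get("soft", False),
                tuple(d["chain_pair"]) if d.get("chain_pair") else None,
            )
            for d in data.get("disulfides", [])
        ],
        metal_sites=[
            MetalSiteSpec(
                label=m["label"],
                ligands=tuple(
                    (lig["pos"], lig["atom"], float(lig["distance"]))
                    for lig in m.get("ligands", [])
                ),
                water_count=m.get("water_ligands", {}).get("count", 0),
                water_distance=m.get("water_ligands", {}).get("distance", 1.94),
                element=m.get("element", "CU"),
                notes=m.get("notes", ""),
            )
            for m in data.get("metal_sites", [])
        ],
        ss_prediction=data.get("ss_prediction", "") or "",
        strand_pairs=[
            StrandPairConstraint(
                tuple(sp["range_a"]), tuple(sp["range_b"]),
                sp.get("target_ca_ca", 5.0),
            )
            for sp in data.get("strand_pairs", [])
        ],
        domain_ranges={
            k: tuple(v) for k, v in data.get("domain_ranges", {}).items()
        },
        params=params,
    )
    cs.validate()
    return cs


def load_constraints(path) -> ConstraintSet:
    """Load and fully validate a ConstraintSet from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConstraintError("constraint file must contain a mapping")
    return _cs_from_dict(data)


def save_constraints(cs: ConstraintSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_cs_to_dict(cs), fh, sort_keys=False)
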