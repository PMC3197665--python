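"""Interface interaction classes and SNP structural context."""

import numpy as np
import pytest

from dbhkit.constraints import ConstraintSet, DBH_DOMAIN_RANGES, MetalSiteSpec
from dbhkit.interface_snp import (
    electrostatic_contacts,
    hydrophobic_contacts,
    interface_report,
    interface_table,
    mutate_residue,
    neighborhood,
    parse_variant,
    relative_exposure,
    salt_bridges,
    snp_context,
    snp_table,
)
from dbhkit.structure import Atom, Residue, Structure
from dbhkit.synthdata import (
    gen_chain,
    gen_metal_site,
    make_residue,
    place_residue_pair,
)


def _pair_grid(rows):
    """Many isolated Glu(A)/Lys(B) pairs, each at its own offset.

    rows: list of (pos, distance).
    """
    s = Structure()
    for k, (pos, dist) in enumerate(sorted(rows)):
        pair = place_residue_pair(
            "GLU", "OE1", "LYS", "NZ", dist, pos_a=pos, pos_b=pos
        )
        offset = np.array([0.0, 30.0 * k, 0.0])
        for res in pair.residues():
            for atom in res.atoms:
                atom.coords = atom.coords + offset
            s.add_residue(res)
    return s


class TestChargedContacts:
    def test_inside_and_outside_salt_bridge_cutoff(self):
        assert len(salt_bridges(_pair_grid([(1, 6.5)]))) == 1
        assert salt_bridges(_pair_grid([(1, 7.5)])) == []

    def test_exact_seven_is_inclusive(self):
        assert len(salt_bridges(_pair_grid([(1, 7.0)]))) == 1

    def test_exact_four_excluded_from_electrostatics(self):
        assert electrostatic_contacts(_pair_grid([(1, 4.0)])) == {}

    def test_just_under_four_in_both_chains_lists(self):
        contacts = electrostatic_contacts(_pair_grid([(1, 3.99)]))
        assert contacts == {"A": [1], "B": [1]}

    def test_pair_beyond_both_cutoffs_absent_everywhere(self):
        s = _pair_grid([(1, 8.0)])
        assert salt_bridges(s) == [] and electrostatic_contacts(s) == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_electrostatic_subset_of_salt_bridges(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (pos, float(rng.uniform(2.5, 9.0)))
            for pos in range(1, 1 + rng.integers(2, 6))
        ]
        s = _pair_grid(rows)
        sb = {
            (a[:2], b[:2]) for a, b, _ in salt_bridges(s)
        }
        elec_chains = electrostatic_contacts(s)
        elec_pairs = {
            (("A", p), ("B", p)) for p in elec_chains.get("A", [])
        }
        assert elec_pairs <= sb


class TestHydrophobicContacts:
    def test_planted_leucine_contact(self):
        s = place_residue_pair("LEU", "CD1", "LEU", "CD1", 3.8)
        contacts = hydrophobic_contacts(s)
        assert contacts == {"A": [1], "B": [1]}

    def test_backbone_only_carbons_excluded(self):
        s = place_residue_pair("GLY", "C", "GLY", "C", 3.5)
        assert hydrophobic_contacts(s) == {}

    def test_far_apart_empty(self):
        s = place_residue_pair("LEU", "CD1", "LEU", "CD1", 9.0)
        assert hydrophobic_contacts(s) == {}


class TestInterfaceReport:
    def test_single_chain_rejected(self):
        s = gen_chain("AAAA", None, 0)
        with pytest.raises(ValueError, match="2 chains"):
            interface_report(s, ConstraintSet())

    def _domain_fixture(self, n_total=50, n_domon=13):
        # planted salt-bridge pairs; n_domon positions inside DOMON (57-173)
        domon_positions = list(range(60, 60 + n_domon))
        outside_positions = list(range(200, 200 + (n_total - n_domon)))
        rows = [(p, 3.5) for p in domon_positions + outside_positions]
        return _pair_grid(rows)

    def test_domon_share_mirrors_planted_fraction(self):
        s = self._domain_fixture()
        cs = ConstraintSet(domain_ranges=dict(DBH_DOMAIN_RANGES))
        report = interface_report(s, cs)
        assert report.domain_share_unique["DOMON"] == pytest.approx(0.26)

    def test_all_contacts_in_one_domain_share_is_one(self):
        rows = [(p, 3.5) for p in (60, 70, 80)]
        cs = ConstraintSet(domain_ranges=dict(DBH_DOMAIN_RANGES))
        report = interface_report(_pair_grid(rows), cs)
        assert report.domain_share_unique["DOMON"] == pytest.approx(1.0)

    def test_residue_may_appear_in_multiple_classes(self):
        # a 3.5 A Glu-Lys pair is simultaneously electrostatic and salt bridge
        s = _pair_grid([(5, 3.5)])
        report = interface_report(s, ConstraintSet())
        assert report.salt_bridge == {"A": [5], "B": [5]}
        assert report.electrostatic == {"A": [5], "B": [5]}

    def test_table_renders_four_columns(self):
        report = interface_report(_pair_grid([(5, 3.5)]), ConstraintSet())
        table = interface_table(report)
        assert list(table.columns) == [
            "Interchain H-bonds",
            "Salt Bridge",
            "Electrostatic Interactions",
            "Hydrophobic Interactions",
        ]


class TestMutation:
    def test_ala_to_ser_grows_og_stub(self):
        s = gen_chain("AAAAA", None, 1)
        m = mutate_residue(s, 3, "A", "SER")
        res = m.residue("A", 3)
        assert res.res_name == "SER" and res.has_atom("OG")
        d = np.linalg.norm(res.atom("OG").coords - res.atom("CB").coords)
        assert d == pytest.approx(1.417, abs=1e-6)

    def test_identity_mutation_is_noop(self):
        s = gen_chain("GGGGG", None, 1)
        m = mutate_residue(s, 3, "A", "GLY")
        assert np.abs(m.atom_coords() - s.atom_coords()).max() == 0.0

    def test_backbone_untouched_so_neighborhood_stable(self):
        s = gen_chain("AAAAAAA", None, 2)
        before = {r[:2] for r in neighborhood(s, 4, "A", 6.0)}
        m = mutate_residue(s, 4, "A", "SER")
        after = {r[:2] for r in neighborhood(m, 4, "A", 6.0)}
        assert before == after

    def test_unknown_type_rejected(self):
        s = gen_chain("AAA", None, 0)
        with pytest.raises(ValueError, match="unknown residue"):
            mutate_residue(s, 1, "A", "XYZ")


class TestNeighborhood:
    def test_isolated_residue_sees_only_itself(self):
        s = Structure()
        s.add_residue(make_residue("ALA", "A", 1))
        far = make_residue("ALA", "A", 2)
        for atom in far.atoms:
            atom.coords = atom.coords + 50.0
        s.add_residue(far)
        assert [r[:2] for r in neighborhood(s, 1, "A")] == [("A", 1)]

    def test_symmetric(self):
        s = gen_chain("AAAAAAAAAA", None, 3)
        for p in range(1, 11):
            for c, q, _ in neighborhood(s, p, "A"):
                assert ("A", p) in {r[:2] for r in neighborhood(s, q, c)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_residue_scan(self, seed):
        from scipy.spatial.distance import cdist

        s = gen_chain("ACDEFGHIKL", None, seed)
        target = s.residue("A", 4)
        tc = np.array([a.coords for a in target.atoms])
        want = {
            ("A", r.seq_pos)
            for r in s.residues()
            if cdist(tc, np.array([a.coords for a in r.atoms])).min() <= 6.0
        }
        got = {r[:2] for r in neighborhood(s, 4, "A", 6.0)}
        assert got == want


class TestSnpContext:
    def test_metal_ligand_in_neighborhood_is_active_site_proximal(self):
        spec = MetalSiteSpec(
            "CuA", ((262, "ND1", 1.96), (263, "ND1", 1.97), (333, "ND1", 2.07))
        )
        s = gen_metal_site(spec, 0)
        cs = ConstraintSet(metal_sites=[spec])
        ctx = snp_context(s, cs, None, (262, "H", "R"), chain="A")
        assert ctx.significance == "active-site-proximal"
        assert ("A", 262) in {r[:2] for r in ctx.neighborhood}
        assert ctx.dist_to_nearest_metal < 8.0

    def test_exposed_cysteine_substitution_flagged(self):
        s = Structure()
        s.add_residue(make_residue("ARG", "A", 549))
        ctx = snp_context(s, ConstraintSet(), None, (549, "R", "C"), chain="A")
        assert ctx.surface_flag
        assert ctx.significance == "surface-cysteine-risk"

    def test_buried_variant_without_context_is_likely_neutral(self):
        s = Structure()
        s.add_residue(make_residue("ALA", "A", 10))
        # bury the variant under a shell of neighbors
        rng = np.random.default_rng(0)
        pos = 11
        for phi in np.linspace(0, np.pi, 4)[1:-1]:
            for theta in np.linspace(0, 2 * np.pi, 9)[:-1]:
                direction = np.array(
                    [
                        np.sin(phi) * np.cos(theta),
                        np.sin(phi) * np.sin(theta),
                        np.cos(phi),
                    ]
                )
                shell = make_residue("GLY", "B", pos, origin=4.0 * direction)
                pos += 1
                s.add_residue(shell)
        ctx = snp_context(s, ConstraintSet(), None, (10, "A", "S"), chain="A")
        assert ctx.significance == "likely-neutral"

    def test_interface_proximal(self):
        s = _pair_grid([(5, 3.5)])
        cs = ConstraintSet()
        report = interface_report(s, cs)
        ctx = snp_context(s, cs, report, (5, "E", "Q"), chain="A")
        assert ctx.significance == "interface-proximal"
        assert ctx.dist_to_interface == 0.0

    def test_missing_position_rejected(self):
        s = gen_chain("AAA", None, 0)
        with pytest.raises(KeyError):
            snp_context(s, ConstraintSet(), None, (99, "A", "S"))

    def test_reference_mismatch_rejected(self):
        s = gen_chain("AAA", None, 0)
        with pytest.raises(ValueError, match="mismatch"):
            snp_context(s, ConstraintSet(), None, (2, "G", "S"))

    def test_table_rendering(self):
        s = Structure()
        s.add_residue(make_residue("ARG", "A", 549))
        ctx = snp_context(s, ConstraintSet(), None, (549, "R", "C"), chain="A")
        table = snp_table([ctx])
        assert table.iloc[0]["SNP"] == "Arg549→Cys549"
        assert "Arg549" in table.iloc[0]["Residues in 6 Å radius"]


def test_parse_variant():
    assert parse_variant("G482R") == (482, "G", "R", "A")
    assert parse_variant("A318S:B") == (318, "A", "S", "B")


def test_relative_exposure_range(rng):
    s = gen_chain("ACDEFG", None, 1)
    exposure = relative_exposure(s)
    assert set(exposure) == {("A", p) for p in range(1, 7)}
    assert all(v >= 0.0 for v in exposure.values())
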