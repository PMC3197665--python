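"""Disulfide, metal-site, Ramachandran, H-bond, SS and clash assessment."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dbhkit.assembly import TorsionSet, build_backbone
from dbhkit.constraints import (
    AnalysisParams,
    ConstraintSet,
    DisulfideConstraint,
    MetalSiteSpec,
)
from dbhkit.geometry import (
    analyze_metal_site,
    assign_ss,
    classify_rama,
    clashes,
    find_disulfides,
    hbonds,
    place_metal,
    ramachandran,
    ss_agreement,
    validate_disulfides,
)
from dbhkit.structure import Atom, Residue, Structure, rigid_transform
from dbhkit.synthdata import gen_chain, gen_metal_site, place_residue_pair


def _cys_cloud(pairs, chain="A"):
    """Chain of Cys residues (SG only + CA) with planted SG-SG distances."""
    s = Structure()
    pos = 1
    offset = 0.0
    for d in pairs:
        for k, x in enumerate((0.0, d)):
            s.add_residue(
                Residue(
                    chain, pos, "CYS",
                    [
                        Atom("CA", np.array([x, offset, 3.0])),
                        Atom("SG", np.array([x, offset, 0.0])),
                    ],
                )
            )
            pos += 1
        offset += 25.0
    return s


class TestDisulfides:
    def test_no_cys_empty_detection(self):
        s = gen_chain("AAAA", None, 0)
        assert find_disulfides(s) == []

    def test_detection_matches_brute_force(self, rng):
        s = Structure()
        coords = rng.uniform(-8, 8, size=(30, 3))
        for i, c in enumerate(coords):
            s.add_residue(Residue("A", i + 1, "CYS", [Atom("SG", c)]))
        got = {(a[1], b[1]) for a, b, _ in find_disulfides(s, 2.5)}
        want = {
            (i + 1, j + 1)
            for i in range(30)
            for j in range(i + 1, 30)
            if np.linalg.norm(coords[i] - coords[j]) <= 2.5
        }
        assert got == want

    def test_soft_pair_reported_separately(self):
        # six satisfied bonds plus one soft pair left open
        s = _cys_cloud([2.05] * 6 + [8.0])
        constraints = [
            DisulfideConstraint(2 * k + 1, 2 * k + 2) for k in range(6)
        ] + [DisulfideConstraint(13, 14, soft=True)]
        cs = ConstraintSet(disulfides=constraints)
        report = validate_disulfides(s, cs)
        assert list(report.statuses.values()) == ["satisfied"] * 6
        assert report.soft_statuses == {(13, 14): "violated"}
        assert report.all_hard_satisfied

    def test_missing_atom_status(self):
        s = Structure()
        s.add_residue(Residue("A", 1, "CYS", [Atom("CA", np.zeros(3))]))
        s.add_residue(Residue("A", 2, "CYS", [Atom("CA", np.ones(3))]))
        cs = ConstraintSet(disulfides=[DisulfideConstraint(1, 2)])
        report = validate_disulfides(s, cs)
        assert report.statuses == {(1, 2): "missing-atom"}


class TestPlaceMetal:
    def test_three_ligands_on_circle_residual_tiny(self):
        s = Structure()
        for i, ang in enumerate((0.0, 2.0 * np.pi / 3, 4.0 * np.pi / 3)):
            s.add_residue(
                Residue(
                    "A", i + 1, "HIS",
                    [Atom("ND1", np.array([np.cos(ang), np.sin(ang), 0.0]))],
                )
            )
        spec = MetalSiteSpec("user", ((1, "ND1", 2.0), (2, "ND1", 2.0), (3, "ND1", 2.0)))
        out = place_metal(s, spec)
        metal = next(a for _, a in out.atoms() if a.element == "CU")
        dists = [
            np.linalg.norm(metal.coords - out.residue("A", i).atom("ND1").coords)
            for i in (1, 2, 3)
        ]
        np.testing.assert_allclose(dists, 2.0, atol=1e-6)
        # on the perpendicular axis through the circle center
        assert abs(metal.coords[0]) < 1e-6 and abs(metal.coords[1]) < 1e-6

    def test_single_ligand_forces_distance(self):
        s = Structure()
        s.add_residue(
            Residue("A", 1, "HIS", [Atom("ND1", np.array([1.0, 2.0, 3.0]))])
        )
        spec = MetalSiteSpec("user", ((1, "ND1", 1.94),))
        out = place_metal(s, spec)
        metal = next(a for _, a in out.atoms() if a.element == "CU")
        d = np.linalg.norm(metal.coords - np.array([1.0, 2.0, 3.0]))
        assert d == pytest.approx(1.94, abs=1e-9)

    def test_replacement_recovers_generated_site(self):
        spec = MetalSiteSpec(
            "CuA", ((262, "ND1", 1.96), (263, "ND1", 1.97), (333, "ND1", 2.07))
        )
        site = gen_metal_site(spec, 0)
        original = next(a for _, a in site.atoms() if a.element == "CU").coords
        stripped = Structure()
        for res in site.residues():
            if not res.is_hetero:
                stripped.add_residue(res)
        replaced = place_metal(stripped, spec)
        new = next(a for _, a in replaced.atoms() if a.element == "CU").coords
        assert np.linalg.norm(new - original) < 1e-3

    def test_stochastic_optimality(self, rng):
        spec = MetalSiteSpec(
            "CuA", ((262, "ND1", 1.96), (263, "ND1", 1.97), (333, "ND1", 2.07))
        )
        site = gen_metal_site(spec, 1)
        stripped = Structure()
        for res in site.residues():
            if not res.is_hetero:
                stripped.add_residue(res)
        placed = place_metal(stripped, spec)
        metal = next(a for _, a in placed.atoms() if a.element == "CU").coords
        pts = np.array(
            [stripped.residue("A", p).atom(n).coords for p, n, _ in spec.ligands]
        )
        targets = np.array([t for _, _, t in spec.ligands])

        def residual(p):
            return np.sum((np.linalg.norm(pts - p, axis=1) - targets) ** 2)

        ours = residual(metal)
        candidates = rng.uniform(-4, 4, size=(1000, 3))
        assert all(residual(c) >= ours - 1e-12 for c in candidates)


class TestAnalyzeMetalSite:
    def test_cua_fixture_ligands_exact(self):
        spec = MetalSiteSpec(
            "CuA",
            ((262, "ND1", 1.96), (263, "ND1", 1.97), (333, "ND1", 2.07)),
            water_count=1,
            water_distance=1.94,
        )
        report = analyze_metal_site(gen_metal_site(spec, 0))[0]
        dists = sorted(round(entry[4], 6) for entry in report.ligands)
        assert dists == [1.94, 1.96, 1.97, 2.07]
        assert [e[4] for e in report.ligands] == sorted(
            e[4] for e in report.ligands
        )

    def test_metal_separation_flag(self):
        spec = MetalSiteSpec("user", ((1, "ND1", 1.99),))
        for sep, expected in ((10.27, True), (6.9, False)):
            from dbhkit.synthdata import gen_two_metal_sites

            s = gen_two_metal_sites(spec, spec, sep, 0)
            reports = analyze_metal_site(s)
            assert all(r.min_cu_cu_respected is expected for r in reports)
            for r in reports:
                assert list(r.metal_metal.values())[0] == pytest.approx(sep, abs=1e-6)

    def test_no_metal_rejected(self):
        with pytest.raises(ValueError, match="no metal"):
            analyze_metal_site(gen_chain("AAA", None, 0))


class TestRamachandran:
    def test_ideal_helix_fully_favored(self):
        s = build_backbone("A" * 12, TorsionSet.uniform(12, -57.0, -47.0))
        report = ramachandran(s)
        assert report.fractions["favored"] == 1.0

    def test_sheet_favored_and_left_quadrant_outlier(self):
        assert classify_rama(-120.0, 120.0) == "favored"
        assert classify_rama(60.0, -150.0) == "outlier"
        # glycine is permissive where general residues are not
        assert classify_rama(80.0, -170.0, "GLY") != "outlier"

    def test_fractions_sum_to_one(self):
        s = gen_chain("ACDEFGHIKLMNPQ", None, 9)
        report = ramachandran(s)
        assert sum(report.fractions.values()) == pytest.approx(1.0)

    def test_invariant_under_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        s = gen_chain("ACDEFGHIKLMNPQRS", None, 4)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = rigid_transform(s, rot, rng.uniform(-9, 9, size=3))
        assert ramachandran(s).fractions == ramachandran(moved).fractions


class TestHbonds:
    def test_planted_pair_reported(self):
        s = place_residue_pair("SER", "OG", "GLU", "OE1", 2.9)
        found = hbonds(s)
        assert any(
            d == pytest.approx(2.9, abs=1e-6) for _, _, d, _ in found
        )

    def test_long_tyrosine_contact_not_reported(self):
        # a 4.56 A hydroxyl-carboxylate separation is beyond H-bond range
        s = place_residue_pair("TYR", "OH", "GLU", "OE1", 4.56)
        assert all(d <= 3.5 for _, _, d, _ in hbonds(s))

    def test_bad_donor_angle_rejected(self):
        s = Structure()
        # donor N with antecedent CA at 90 degrees to the acceptor
        s.add_residue(
            Residue(
                "A", 1, "GLY",
                [Atom("N", np.zeros(3)), Atom("CA", np.array([1.47, 0, 0]))],
            )
        )
        s.add_residue(
            Residue("B", 1, "HOH",
                    [Atom("O", np.array([0.0, 3.4, 0.0]), "O", is_hetero=True)])
        )
        assert hbonds(s) == []

    def test_distance_symmetric_between_entities(self):
        s = place_residue_pair("SER", "OG", "THR", "OG1", 3.0)
        found = hbonds(s)
        dists = {round(d, 6) for _, _, d, _ in found}
        assert dists == {3.0}


class TestSecondaryStructure:
    def test_ideal_helix_all_h_and_full_agreement(self):
        s = build_backbone("A" * 10, TorsionSet.uniform(10, -57.0, -47.0))
        assigned = assign_ss(s)
        assert set(assigned[1:-1]) == {"H"}
        assert ss_agreement("H" * 10, "H" * 10) == 100.0

    def test_extended_vs_helix_prediction_zero_agreement(self):
        s = build_backbone("A" * 10, TorsionSet.uniform(10, -120.0, 120.0))
        assigned = assign_ss(s)
        assert ss_agreement(assigned[1:-1], "H" * 8) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_generator_consistency(self, seed):
        ss = "LLHHHHHHHLLLEEEEELLLHHHHLL"
        s = gen_chain("A" * len(ss), ss, seed)
        assert ss_agreement(assign_ss(s), ss) >= 90.0


class TestClashes:
    def test_ideal_extended_chain_clash_free(self):
        s = build_backbone("A" * 15, TorsionSet.uniform(15, 180.0, 180.0),
                           sidechains=True)
        assert clashes(s) == []

    def test_planted_interchain_clash(self):
        s = Structure()
        s.add_residue(Residue("A", 1, "GLY", [Atom("CA", np.zeros(3))]))
        s.add_residue(
            Residue("B", 1, "GLY", [Atom("CA", np.array([2.0, 0, 0]))])
        )
        found = clashes(s)
        assert len(found) == 1 and found[0][2] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = Structure()
        coords = rng.uniform(-6, 6, size=(40, 3))
        for i, c in enumerate(coords):
            s.add_residue(Residue("A", i + 1, "GLY", [Atom("CA", c)]))
        got = {(a[1], b[1]) for a, b, _ in clashes(s, 2.4)}
        want = {
            (i + 1, j + 1)
            for i in range(40)
            for j in range(i + 1, 40)
            if j - i > 2 and np.linalg.norm(coords[i] - coords[j]) < 2.4
        }
        assert got == want
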