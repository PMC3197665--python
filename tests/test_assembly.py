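"""Backbone construction, torsion extraction and assembly searches."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from dbhkit.assembly import (
    AssemblyScore,
    RigidTransform,
    TorsionSet,
    assemble_dimer,
    assemble_tetramer,
    build_backbone,
    dihedral,
    extract_torsions,
    graft_fragment,
    linker_search,
)
from dbhkit.constraints import ConstraintSet, DisulfideConstraint, StrandPairConstraint
from dbhkit.structure import rigid_transform
from dbhkit.synthdata import gen_chain


def _random_torsions(rng, n):
    phi = rng.uniform(-179.0, 180.0, size=n)
    psi = rng.uniform(-179.0, 180.0, size=n)
    omega = np.full(n, 180.0)
    phi[0] = psi[-1] = omega[0] = np.nan
    return TorsionSet(phi, psi, omega)


def _oracle_dihedral(p0, p1, p2, p3):
    """Plane-normal formulation, independent of the NeRF route: the angle
    between the (p0,p1,p2) and (p1,p2,p3) planes, signed along p1->p2."""
    b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1)
    return math.degrees(math.atan2(y, x))


class TestBackbone:
    def test_fully_extended_ca_spacing(self):
        s = build_backbone("A" * 10, TorsionSet.uniform(10, 180.0, 180.0))
        ca = np.array([s.residue("A", i + 1).atom("CA").coords for i in range(10)])
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.80, atol=0.02)

    def test_helix_rise_per_residue(self):
        s = build_backbone("A" * 18, TorsionSet.uniform(18, -57.0, -47.0))
        ca = np.array([s.residue("A", i + 1).atom("CA").coords for i in range(18)])
        rise = np.linalg.norm(ca[-1] - ca[0]) / 17
        assert rise == pytest.approx(1.5, abs=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_backbone("AAA", TorsionSet.uniform(4, 180.0, 180.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_to_microdegree(self, seed):
        rng = np.random.default_rng(seed)
        t = _random_torsions(rng, 12)
        s = build_backbone("ACDEFGHIKLMN", t)
        back = extract_torsions(s)
        for a, b in ((t.phi, back.phi), (t.psi, back.psi), (t.omega, back.omega)):
            mask = ~np.isnan(a)
            diff = np.abs(a[mask] - b[mask])
            diff = np.minimum(diff, 360.0 - diff)
            assert diff.max() < 1e-6

    def test_extract_requires_backbone(self):
        s = build_backbone("AAAA", TorsionSet.uniform(4, 180.0, 180.0))
        res = s.residue("A", 2)
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(ValueError, match="CA"):
            extract_torsions(s)

    def test_extracted_extended_fixture_near_180(self):
        s = build_backbone("A" * 6, TorsionSet.uniform(6, 180.0, 180.0))
        t = extract_torsions(s)
        assert abs(abs(t.phi[2]) - 180.0) < 1e-9
        assert abs(abs(t.psi[2]) - 180.0) < 1e-9


class TestDihedral:
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_plane_normal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            pts = rng.uniform(-5, 5, size=(4, 3))
            if np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[1])) < 1e-3:
                continue
            got = dihedral(*pts)
            want = _oracle_dihedral(*pts)
            diff = abs(got - want)
            assert min(diff, 360 - diff) < 1e-9


class TestRigidTransform:
    def test_rotation_must_be_proper(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rigid_ops_preserve_intrachain_distances(self, rng):
        s = gen_chain("ACDEFG", None, 5)
        before = cdist(s.atom_coords(), s.atom_coords())
        rt = RigidTransform.from_rotvec(rng.normal(size=3), rng.normal(size=3))
        after_s = rt.apply(s)
        after = cdist(after_s.atom_coords(), after_s.atom_coords())
        assert np.abs(after - before).max() < 1e-6


class TestGraft:
    def test_identity_graft_leaves_structure_unchanged(self):
        s = build_backbone("A" * 12, TorsionSet.uniform(12, -57.0, -47.0))
        frag = build_backbone("A" * 4, TorsionSet.uniform(4, -57.0, -47.0))
        g = graft_fragment(s, frag, (5, 8))
        diff = np.abs(g.atom_coords() - s.atom_coords()).max()
        assert diff < 1e-6

    def test_helix_graft_sets_exact_torsions(self):
        s = build_backbone("A" * 20, TorsionSet.uniform(20, 180.0, 180.0))
        frag = build_backbone("A" * 6, TorsionSet.uniform(6, -57.0, -47.0))
        g = graft_fragment(s, frag, (8, 13))
        t = extract_torsions(g)
        np.testing.assert_allclose(t.phi[8:13], -57.0, atol=1e-6)

    def test_fragment_internal_geometry_preserved_rigidly(self):
        s = build_backbone("A" * 30, TorsionSet.uniform(30, 180.0, 180.0))
        frag = gen_chain("A" * 8, "LHHHHHHL", seed=2)
        g = graft_fragment(s, frag, (10, 17))
        got = np.array(
            [g.residue("A", p).atom("CA").coords for p in range(10, 18)]
        )
        ref = np.array(
            [frag.residue("A", p).atom("CA").coords for p in range(1, 9)]
        )
        d_got = cdist(got, got)
        d_ref = cdist(ref, ref)
        assert np.abs(d_got - d_ref).max() < 1e-6

    def test_range_length_mismatch_rejected(self):
        s = build_backbone("A" * 10, TorsionSet.uniform(10, 180.0, 180.0))
        frag = build_backbone("A" * 3, TorsionSet.uniform(3, 180.0, 180.0))
        with pytest.raises(ValueError, match="length"):
            graft_fragment(s, frag, (2, 8))


class TestLinkerSearch:
    def _toy(self, seed):
        seq = "CAAAAAAAAAAC"
        s = gen_chain(seq, "L" * 12, seed=seed)
        cs = ConstraintSet(sequence=seq, disulfides=[DisulfideConstraint(1, 12)])
        return s, cs

    def test_closes_toy_disulfide(self):
        s, cs = self._toy(3)
        out, score = linker_search(s, (2, 11), cs, iters=1500, seed=3)
        d = np.linalg.norm(
            out.residue("A", 1).atom("SG").coords
            - out.residue("A", 12).atom("SG").coords
        )
        assert d <= 2.35
        assert score.clash_penalty == 0

    def test_already_satisfied_returns_unchanged(self):
        s, cs = self._toy(3)
        closed, _ = linker_search(s, (2, 11), cs, iters=1500, seed=3)
        again, score = linker_search(closed, (2, 11), cs, iters=100, seed=0)
        assert score.total <= 0.04
        assert np.abs(again.atom_coords() - closed.atom_coords()).max() < 1e-9

    def test_unconstrained_search_rejected(self):
        s, _ = self._toy(0)
        cs = ConstraintSet(sequence="CAAAAAAAAAAC")
        with pytest.raises(ValueError, match="unconstrained"):
            linker_search(s, (2, 11), cs)

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_non_increasing(self, seed):
        s, cs = self._toy(seed)
        _, score = linker_search(s, (2, 11), cs, iters=300, seed=seed)
        trace = np.array(score.trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_strand_pair_closure_on_toy(self):
        # miniature re-enactment of pairing an N-terminal strand with a
        # downstream one across a flexible linker
        n = 40
        seq = "A" * n
        ss = "LEEEE" + "L" * 30 + "EEEEL"
        s = gen_chain(seq, ss, seed=1)
        cs = ConstraintSet(
            sequence=seq,
            strand_pairs=[StrandPairConstraint((2, 5), (36, 39), target_ca_ca=5.0)],
        )
        out, score = linker_search(s, (8, 33), cs, iters=6000, seed=5,
                                   stop_tol=1.0, restarts=3)
        for i, j in cs.strand_pairs[0].pairs():
            d = np.linalg.norm(
                out.residue("A", i).atom("CA").coords
                - out.residue("A", j).atom("CA").coords
            )
            assert d <= 6.0


class TestDimerAssembly:
    def _chains(self):
        seq = "AACACAAAAA"
        a = build_backbone(seq, TorsionSet.uniform(10, 180.0, 180.0), "A",
                           sidechains=True)
        b = build_backbone(seq, TorsionSet.uniform(10, 180.0, 180.0), "B",
                           sidechains=True)
        return a, b

    def test_double_disulfide_constraint_satisfied(self):
        a, b = self._chains()
        cons = [
            DisulfideConstraint(3, 3, scope="interchain"),
            DisulfideConstraint(5, 5, scope="interchain"),
        ]
        merged, score = assemble_dimer(a, b, cons, iters=10, seed=0)
        assert all(d <= 3.0 for d in score.achieved_distances)
        assert score.clash_penalty == 0
        assert sorted(merged.chain_ids) == ["A", "B"]

    def test_preplaced_optimum_scores_near_zero(self):
        a, b = self._chains()
        cons = [DisulfideConstraint(3, 3, scope="interchain")]
        merged, _ = assemble_dimer(a, b, cons, iters=8, seed=1)
        # re-assemble starting from the already optimal placement
        a2 = Structure_from_chain(merged, "A")
        b2 = Structure_from_chain(merged, "B")
        _, score = assemble_dimer(a2, b2, cons, iters=1, seed=0)
        assert score.total < 0.05

    def test_missing_sg_rejected(self):
        a = build_backbone("AAAA", TorsionSet.uniform(4, 180.0, 180.0), "A",
                           sidechains=True)
        b = build_backbone("AAAA", TorsionSet.uniform(4, 180.0, 180.0), "B",
                           sidechains=True)
        with pytest.raises(ValueError, match="SG"):
            assemble_dimer(a, b, [DisulfideConstraint(2, 2, scope="interchain")])


def Structure_from_chain(structure, chain_id):
    from dbhkit.structure import Structure

    out = Structure()
    for res in structure.residues(chain_id):
        out.add_residue(res)
    return out.copy()


class TestTetramerAssembly:
    def test_chain_collision_rejected(self):
        a = gen_chain("AAAA", None, 0, chain_id="A")
        b = gen_chain("AAAA", None, 1, chain_id="A")
        with pytest.raises(ValueError, match="collision"):
            assemble_tetramer(a, b)

    def test_no_hints_gives_clash_free_placement(self):
        d1 = gen_chain("AAAAAA", None, 0, chain_id="A")
        d2 = gen_chain("AAAAAA", None, 1, chain_id="C")
        merged, score = assemble_tetramer(d1, d2, None, iters=4, seed=0)
        assert score.clash_penalty == 0

    def test_hint_contacts_brought_close(self):
        d1 = gen_chain("AAAAAAAA", None, 0, chain_id="A")
        d2 = gen_chain("AAAAAAAA", None, 1, chain_id="C")
        hints = [("A", 4, "CB", "C", 4, "CB")]
        merged, score = assemble_tetramer(d1, d2, hints, iters=10, seed=0)
        assert score.achieved_distances[0] <= 4.5
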