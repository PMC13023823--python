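"""Node coordinates, inter-branch angles, skeleton reconstruction and RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rna3wj.errors import DegenerateGeometryError, UnresolvableNodeError
from rna3wj.geometry import (AngleSet, SkeletonStar, angle_between,
                             compute_inter_branch_angles, extract_chain_geometry,
                             junction_anchor, loop_node_coordinate, native_star,
                             node_coordinates, read_structure, realized_angles,
                             reconstruct_skeleton, skeleton_rmsd,
                             triangle_incenter)
from rna3wj.secstruct import build_tree_graph, parse_dot_bracket


def random_feasible_angles(rng):
    """Angle triples realized by random unit directions are always feasible."""
    while True:
        u = rng.normal(size=(3, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        t1 = angle_between(u[0], u[1])
        t2 = angle_between(u[1], u[2])
        t3 = angle_between(u[2], u[0])
        if min(t1, t2, t3) > 2.0 and max(t1, t2, t3) < 178.0:
            return AngleSet(t1, t2, t3), u


class TestIncenter:
    def test_right_triangle_closed_form(self):
        # legs 3 and 4: inradius r = (3 + 4 - 5)/2 = 1 -> incenter (1, 1, 0)
        I = triangle_incenter((0, 0, 0), (4, 0, 0), (0, 3, 0))
        assert np.allclose(I, (1, 1, 0), atol=1e-9)

    def test_equilateral_is_centroid(self):
        A = np.array([1.0, 0, 0])
        B = np.array([-0.5, math.sqrt(3) / 2, 0])
        C = np.array([-0.5, -math.sqrt(3) / 2, 0])
        assert np.allclose(triangle_incenter(A, B, C), (A + B + C) / 3, atol=1e-9)

    def test_translation_equivariance(self):
        t = np.array([2.0, -1.0, 5.0])
        I0 = triangle_incenter((0, 0, 0), (4, 0, 0), (0, 3, 0))
        I1 = triangle_incenter(t, (4, 0, 0) + t, (0, 3, 0) + t)
        assert np.allclose(I1, I0 + t, atol=1e-9)

    def test_degenerate_falls_back_to_centroid(self):
        I = triangle_incenter((0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert np.allclose(I, (1, 0, 0))


class TestAngleBetween:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (1, 0, 0), 0.0),
        ((1, 1, 0), (1, 0, 0), 45.0),
    ])
    def test_examples(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            angle_between((0, 0, 0), (1, 0, 0))


class TestNodeCoordinates:
    def test_loop_centroid_and_anchor_midpoint(self):
        ss = parse_dot_bracket("((..))", "GGAACC")
        tree = build_tree_graph(ss)
        coords = {k: np.array([float(k), 0.0, 0.0]) for k in range(6)}
        h = next(m for m in tree.motifs if m.kind == "H")
        assert np.allclose(loop_node_coordinate(h, coords), (2.5, 0, 0))
        assert np.allclose(junction_anchor((0, 5), coords), (2.5, 0, 0))

    def test_unresolvable_loop(self):
        ss = parse_dot_bracket("((..))", "GGAACC")
        tree = build_tree_graph(ss)
        h = next(m for m in tree.motifs if m.kind == "H")
        with pytest.raises(UnresolvableNodeError):
            loop_node_coordinate(h, {0: np.zeros(3)})


class TestInterBranchAngles:
    def _tiny_junction(self):
        db = ".((.((...)).((...)).))."
        ss = parse_dot_bracket(db, "A" * len(db))
        tree = build_tree_graph(ss)
        from rna3wj.secstruct import find_three_way_junctions

        (j,) = find_three_way_junctions(tree)
        return ss, tree, j

    def _coords_with_neighbors(self, tree, j, dirs):
        """Node coordinates: junction at origin, neighbors along dirs."""
        nc = {j.node_id: np.zeros(3)}
        for nb, d in zip(j.neighbors, dirs):
            nc[nb] = np.asarray(d, dtype=float)
        return nc

    def test_orthogonal_and_symmetric(self):
        ss, tree, j = self._tiny_junction()
        nc = self._coords_with_neighbors(tree, j, [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        a = compute_inter_branch_angles(j, tree, nc)
        assert np.allclose(a.as_array(), 90.0, atol=1e-9)
        y = [(1, 0, 0), (-0.5, math.sqrt(3) / 2, 0), (-0.5, -math.sqrt(3) / 2, 0)]
        a = compute_inter_branch_angles(j, tree, self._coords_with_neighbors(tree, j, y))
        assert np.allclose(a.as_array(), 120.0, atol=1e-6)

    def test_near_linear(self):
        ss, tree, j = self._tiny_junction()
        nc = self._coords_with_neighbors(
            tree, j, [(1, 0, 0), (-1, 1e-9, 0), (0, 0, 1)])
        a = compute_inter_branch_angles(j, tree, nc)
        assert a.theta1 == pytest.approx(180.0, abs=1e-6)
        assert a.theta2 == pytest.approx(90.0, abs=1e-9)
        assert a.theta3 == pytest.approx(90.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        ss, tree, j = self._tiny_junction()
        rng = np.random.default_rng(5)
        dirs = rng.normal(size=(3, 3)) * 10
        nc = self._coords_with_neighbors(tree, j, dirs)
        a0 = compute_inter_branch_angles(j, tree, nc)
        R = Rotation.random(random_state=7).as_matrix()
        t = np.array([3.0, -2.0, 9.0])
        nc2 = {k: R @ v + t for k, v in nc.items()}
        a1 = compute_inter_branch_angles(j, tree, nc2)
        assert np.allclose(a0.as_array(), a1.as_array(), atol=1e-9)

    def test_zero_branch_vector_rejected(self):
        ss, tree, j = self._tiny_junction()
        nc = self._coords_with_neighbors(tree, j, [(0, 0, 0), (0, 1, 0), (0, 0, 1)])
        with pytest.raises(DegenerateGeometryError):
            compute_inter_branch_angles(j, tree, nc)


class TestReconstruct:
    def test_orthogonal(self):
        s = reconstruct_skeleton(AngleSet(90, 90, 90), (1, 1, 1))
        assert np.allclose(s.endpoints[0], (1, 0, 0), atol=1e-12)
        assert np.allclose(s.endpoints[1], (0, 1, 0), atol=1e-12)
        assert np.allclose(s.endpoints[2], (0, 0, 1), atol=1e-12)
        assert s.feasible

    def test_sixty_degrees(self):
        s = reconstruct_skeleton(AngleSet(60, 60, 60), (1, 1, 1))
        assert np.allclose(s.endpoints[2], (0.5, 0.288675, 0.816497), atol=1e-6)
        u = [e / np.linalg.norm(e) for e in s.endpoints]
        for a, b in ((0, 1), (1, 2), (2, 0)):
            assert np.dot(u[a], u[b]) == pytest.approx(0.5, abs=1e-12)

    def test_infeasible_clipped_and_flagged(self):
        s = reconstruct_skeleton(AngleSet(10, 10, 170), (1, 1, 1))
        assert not s.feasible
        r = realized_angles(s)
        assert np.allclose(r.as_array(), (10, 10, 20), atol=1e-9)

    def test_branch_length_invariant(self):
        s = reconstruct_skeleton(AngleSet(70, 120, 95), (2.0, 3.5, 11.0))
        for e, L in zip(s.endpoints, (2.0, 3.5, 11.0)):
            assert np.linalg.norm(e - s.center) == pytest.approx(L, abs=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            reconstruct_skeleton(AngleSet(90, 90, 90), (1, 0, 1))


class TestRoundTripProperty:
    def test_realized_equals_input_on_feasible_triples(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            angles, _ = random_feasible_angles(rng)
            star = reconstruct_skeleton(angles, rng.uniform(1, 20, size=3))
            r = realized_angles(star)
            assert np.allclose(r.as_array(), angles.as_array(), atol=1e-6)


class TestSkeletonRmsd:
    def test_identical_zero(self):
        s = reconstruct_skeleton(AngleSet(80, 100, 120), (3, 4, 5))
        assert skeleton_rmsd(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        s = reconstruct_skeleton(AngleSet(80, 100, 120), (3, 4, 5))
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        moved = SkeletonStar(R @ s.center + t,
                             tuple(R @ e + t for e in s.endpoints),
                             s.branch_lengths, True)
        assert skeleton_rmsd(s, moved) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_counts_as_congruent(self):
        s = reconstruct_skeleton(AngleSet(80, 100, 120), (3, 4, 5))
        mirrored = SkeletonStar(s.center,
                                tuple(e * np.array([1, 1, -1.0]) for e in s.endpoints),
                                s.branch_lengths, True)
        assert skeleton_rmsd(s, mirrored) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_and_positivity(self):
        a = reconstruct_skeleton(AngleSet(80, 100, 120), (3, 4, 5))
        b = reconstruct_skeleton(AngleSet(95, 100, 120), (3, 4, 5))
        assert skeleton_rmsd(a, b) == pytest.approx(skeleton_rmsd(b, a), abs=1e-12)
        assert skeleton_rmsd(a, b) > 0.01


class TestReadStructure:
    def test_toy_pdb(self, tmp_path):
        from rna3wj.synthetic import SyntheticRecord, emit_structure_file

        rec = SyntheticRecord(
            record_id="toy", sequence="GCA", dot_bracket="...",
            angles=AngleSet(90, 90, 90), branch_lengths=(1, 1, 1),
            segment_lengths=(0, 0, 0), gc_fractions=(0, 0, 0),
            coords={0: np.zeros(3), 1: np.array([1.0, 0, 0]),
                    2: np.array([2.0, 0, 0])})
        p = tmp_path / "toy.pdb"
        emit_structure_file(rec, p)
        coords = read_structure(p, "A")
        assert len(coords) == 3
        assert np.allclose(coords[1], (1, 0, 0))
        # chain optional when unique; wrong chain errors
        assert len(read_structure(p)) == 3
        with pytest.raises(ValueError, match="chain"):
            read_structure(p, "Q")

    def test_extraction_matches_planted_fixture(self, tmp_path):
        from rna3wj.secstruct import parse_dot_bracket
        from rna3wj.synthetic import SyntheticSpec, emit_structure_file, generate_records

        (rec,) = generate_records(SyntheticSpec(count=1, seed=9))
        p = tmp_path / "syn.pdb"
        emit_structure_file(rec, p)
        ss = parse_dot_bracket(rec.dot_bracket, rec.sequence)
        (geom,) = extract_chain_geometry(ss, read_structure(p, "A"))
        assert np.allclose(geom["angles"].as_array(), rec.angles.as_array(), atol=1e-3)


def test_extracted_angles_satisfy_spherical_constraints():
    """Every extracted triple obeys the triangle inequalities and sum <= 360."""
    from rna3wj.synthetic import SyntheticSpec, generate_records

    for rec in generate_records(SyntheticSpec(count=20, seed=77)):
        t = np.sort(rec.angles.as_array())
        assert t[2] <= t[0] + t[1] + 1e-9
        assert t.sum() <= 360.0 + 1e-9
        assert np.all(t > 0) and np.all(t <= 180)
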