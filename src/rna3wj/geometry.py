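"""Coarse-grained 3D geometry of RNA three-way junctions.

C4' atoms serve as conformationally stable backbone anchors.  Every tree
node receives a spatial coordinate: non-junction loops get the centroid of
their members' C4' atoms; a junction node gets the incenter of the triangle
formed by the three branch anchors (midpoints of the closing base pairs).
Inter-branch angles are measured between the vectors from the junction
coordinate to the three neighboring node coordinates, following the
(1,2), (2,3), (3,1) convention, each in (0, 180] degrees.

A junction abstracted this way is a *rigid star*: a center plus three
endpoints.  Stars can be reconstructed from an angle triple and branch
lengths, and compared by Kabsch-superposed RMSD (minimum over the two
chirality choices, since an angle triple does not fix handedness).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, UnresolvableNodeError
from .secstruct import Motif, SecondaryStructure, Stem, ThreeWayJunction, TreeGraph

log = logging.getLogger(__name__)

C4_NAMES = ("C4'", "C4*")


@dataclass(frozen=True)
class AngleSet:
    """Inter-branch angle triple in degrees.

    theta1 is between Branches 1-2, theta2 between 2-3, theta3 between 3-1.
    Extracted (ground-truth) angles lie in (0, 180]; predicted triples are
    unconstrained.
    """

    theta1: float
    theta2: float
    theta3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)

    @classmethod
    def from_array(cls, a) -> "AngleSet":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class SkeletonStar:
    """4-point rigid-star model of a junction: center + three endpoints."""

    center: np.ndarray
    endpoints: tuple  # three 3-vectors, by branch index
    branch_lengths: tuple
    feasible: bool = True

    def points(self) -> np.ndarray:
        return np.vstack([self.center] + [np.asarray(e) for e in self.endpoints])


def read_structure(path, chain=None) -> dict:
    """Extract one C4' coordinate per resolved residue of a chain.

    Residues are indexed 0-based in chain order, matching the sequence
    positions used throughout the package.  Residues lacking a C4' atom are
    omitted with a warning.

    Parameters
    ----------
    path : PDB or mmCIF file.
    chain : chain name; may be omitted when the file has a single chain.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ValueError(f"{path}: specify a chain (found {names})")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found (available: {names})")
    coords = {}
    for idx, residue in enumerate(model[chain]):
        atom = None
        for name in C4_NAMES:
            atom = residue.find_atom(name, "*")
            if atom is not None:
                break
        if atom is None:
            log.warning("%s %s: residue %d (%s) lacks a C4' atom; skipped",
                        path, chain, idx + 1, residue.name)
            continue
        coords[idx] = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
    if not coords:
        raise ValueError(f"{path} chain {chain}: no C4' atoms found")
    return coords


def loop_node_coordinate(motif: Motif, coords: dict) -> np.ndarray:
    """Centroid of the C4' atoms of a (non-junction) loop's members."""
    members = [coords[k] for k in motif.member_indices() if k in coords]
    if not members:
        raise UnresolvableNodeError(
            f"motif {motif.motif_id} ({motif.kind}): no resolved member residues"
        )
    return np.mean(members, axis=0)


def junction_anchor(closing_pair, coords: dict) -> np.ndarray:
    """Midpoint of the two C4' atoms of a branch's closing base pair."""
    i, j = closing_pair
    if i not in coords or j not in coords:
        raise UnresolvableNodeError(
            f"closing pair ({i + 1},{j + 1}): C4' atom missing"
        )
    return 0.5 * (coords[i] + coords[j])


def triangle_incenter(A, B, C, area_tol: float = 1e-6) -> np.ndarray:
    """Incenter I = (a*A + b*B + c*C)/(a+b+c), a=|BC|, b=|CA|, c=|AB|.

    For a degenerate (collinear) triangle the incenter is undefined; the
    centroid is returned instead with a warning.
    """
    A, B, C = (np.asarray(p, dtype=float) for p in (A, B, C))
    a = np.linalg.norm(B - C)
    b = np.linalg.norm(C - A)
    c = np.linalg.norm(A - B)
    area = 0.5 * np.linalg.norm(np.cross(B - A, C - A))
    if a + b + c < area_tol or area < area_tol:
        log.warning("degenerate anchor triangle (area %.2e); falling back to centroid", area)
        return (A + B + C) / 3.0
    return (a * A + b * B + c * C) / (a + b + c)


def junction_node_coordinate(junction: ThreeWayJunction, coords: dict) -> np.ndarray:
    """Incenter of the triangle formed by the three branch anchors."""
    anchors = [junction_anchor(cp, coords) for cp in junction.closing_pairs]
    return triangle_incenter(*anchors)


def node_coordinates(tree: TreeGraph, coords: dict) -> dict:
    """Assign a 3D coordinate to every resolvable tree node.

    Junction (degree-3 M) nodes use the anchor-triangle incenter, all other
    loops the member centroid.  Unresolvable nodes are skipped with a log
    message.
    """
    from .secstruct import find_three_way_junctions

    out = {}
    junctions = {j.node_id: j for j in find_three_way_junctions(tree)}
    for m in tree.motifs:
        try:
            if m.motif_id in junctions:
                out[m.motif_id] = junction_node_coordinate(junctions[m.motif_id], coords)
            else:
                out[m.motif_id] = loop_node_coordinate(m, coords)
        except UnresolvableNodeError as exc:
            log.warning("node %d unresolvable: %s", m.motif_id, exc)
    return out


def angle_between(u, v) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("angle of a zero vector is undefined")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cos))


def compute_inter_branch_angles(
    junction: ThreeWayJunction,
    tree: TreeGraph,
    node_coords: dict,
    branch_endpoint: str = "node",
    coords: dict = None,
) -> AngleSet:
    """Angles between the three branch direction vectors of a junction.

    Branch direction k points from the junction coordinate to the
    coordinate of the tree node reached via Branch k
    (``branch_endpoint="node"``, the default) or to the branch anchor
    midpoint (``branch_endpoint="anchor"``, requires ``coords``).
    """
    if junction.node_id not in node_coords:
        raise UnresolvableNodeError(f"junction node {junction.node_id} has no coordinate")
    J = node_coords[junction.node_id]
    dirs = []
    for k in range(3):
        if branch_endpoint == "node":
            nb = junction.neighbors[k]
            if nb not in node_coords:
                raise UnresolvableNodeError(f"neighbor node {nb} has no coordinate")
            target = node_coords[nb]
        elif branch_endpoint == "anchor":
            if coords is None:
                raise ValueError("branch_endpoint='anchor' requires residue coords")
            target = junction_anchor(junction.closing_pairs[k], coords)
        else:
            raise ValueError(f"unknown branch_endpoint {branch_endpoint!r}")
        v = target - J
        if np.linalg.norm(v) < 1e-9:
            raise DegenerateGeometryError(
                f"zero-length branch vector for branch {k + 1}"
            )
        dirs.append(v)
    return AngleSet(
        angle_between(dirs[0], dirs[1]),
        angle_between(dirs[1], dirs[2]),
        angle_between(dirs[2], dirs[0]),
    )


def branch_lengths(junction: ThreeWayJunction, node_coords: dict) -> tuple:
    """Euclidean junction-to-neighbor distances (the 3D tree edge lengths)."""
    J = node_coords[junction.node_id]
    return tuple(float(np.linalg.norm(node_coords[nb] - J)) for nb in junction.neighbors)


def native_star(junction: ThreeWayJunction, node_coords: dict) -> SkeletonStar:
    """Rigid star abstracted from native coordinates."""
    J = node_coords[junction.node_id]
    eps = tuple(np.asarray(node_coords[nb], dtype=float) for nb in junction.neighbors)
    lengths = tuple(float(np.linalg.norm(e - J)) for e in eps)
    return SkeletonStar(np.asarray(J, dtype=float), eps, lengths, True)


def branch_directions(angles: AngleSet):
    """Unit branch directions realizing an angle triple, plus feasibility.

    u1 = +x; u2 in the xy-plane at theta1 from u1; u3 fixed by its dot
    products with u1 and u2, out-of-plane component +sqrt(max(0, .)).
    Returns ``(u, feasible)`` where ``feasible`` is False when the square
    root clip was active (Gram matrix of the directions not PSD).
    """
    t1, t2, t3 = np.radians(angles.as_array())
    if abs(math.sin(t1)) < 1e-9:
        log.warning("theta1 ~ 0 or 180 deg; perturbing to avoid a degenerate frame")
        t1 = max(min(t1, math.pi - 1e-7), 1e-7)
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([math.cos(t1), math.sin(t1), 0.0])
    x = math.cos(t3)
    y = (math.cos(t2) - x * math.cos(t1)) / math.sin(t1)
    z2 = 1.0 - x * x - y * y
    feasible = z2 >= -1e-12
    if feasible:
        u3 = np.array([x, y, math.sqrt(max(0.0, z2))])
    else:
        # spherical-triangle constraints violated: embed u3 in-plane,
        # preserving theta2 exactly and taking theta3 to the nearest
        # attainable boundary (theta1 +/- theta2)
        best = None
        for phi in (t1 + t2, t1 - t2):
            realized = abs(math.remainder(phi, 2 * math.pi))
            if best is None or abs(realized - t3) < best[0]:
                best = (abs(realized - t3), phi)
        phi = best[1]
        u3 = np.array([math.cos(phi), math.sin(phi), 0.0])
    return np.vstack([u1, u2, u3]), feasible


def reconstruct_skeleton(angles: AngleSet, lengths) -> SkeletonStar:
    """Rigid star at the origin realizing an angle triple and branch lengths.

    Infeasible triples (violating the spherical constraints) are clipped to
    the nearest embeddable configuration and flagged ``feasible=False``.
    """
    lengths = tuple(float(l) for l in lengths)
    if any(l <= 0 for l in lengths):
        raise DegenerateGeometryError("branch lengths must be positive")
    u, feasible = branch_directions(angles)
    center = np.zeros(3)
    endpoints = tuple(lengths[k] * u[k] for k in range(3))
    return SkeletonStar(center, endpoints, lengths, feasible)


def realized_angles(star: SkeletonStar) -> AngleSet:
    """Pairwise angles recomputed from a star's endpoints."""
    v = [np.asarray(e) - star.center for e in star.endpoints]
    return AngleSet(
        angle_between(v[0], v[1]),
        angle_between(v[1], v[2]),
        angle_between(v[2], v[0]),
    )


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Least-squares rigid-superposition RMSD (proper rotations only)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Pc, Qc)
    return float(rssd) / math.sqrt(len(P))


def skeleton_rmsd(pred: SkeletonStar, native: SkeletonStar) -> float:
    """Kabsch RMSD over the 4 matched star points, minimum over the two
    chirality choices (a predicted angle triple does not fix handedness)."""
    P = pred.points()
    N = native.points()
    mirror = P * np.array([1.0, 1.0, -1.0])
    return min(_kabsch_rmsd(N, P), _kabsch_rmsd(N, mirror))


def extract_chain_geometry(ss: SecondaryStructure, coords: dict,
                           branch_endpoint: str = "node") -> list:
    """Full ground-truth extraction for one chain.

    Returns a list of dicts, one per three-way junction, with the junction
    record, its :class:`AngleSet`, branch lengths and native star.
    Junctions with unresolvable nodes are skipped with a log message.
    """
    from .secstruct import build_tree_graph, find_three_way_junctions

    tree = build_tree_graph(ss)
    ncoords = node_coordinates(tree, coords)
    out = []
    for j in find_three_way_junctions(tree):
        try:
            angles = compute_inter_branch_angles(j, tree, ncoords, branch_endpoint, coords)
        except (UnresolvableNodeError, DegenerateGeometryError) as exc:
            log.warning("junction %d skipped: %s", j.node_id, exc)
            continue
        out.append({
            "junction": j,
            "angles": angles,
            "branch_lengths": branch_lengths(j, ncoords),
            "native_star": native_star(j, ncoords),
        })
    return out
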