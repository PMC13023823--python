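"""Synthetic single-junction RNAs with planted, recoverable 3D geometry.

Each generated chain has the layout::

    5' ext - stem1 - segA - stem2 - hairpin1 - stem2' - segB
           - stem3 - hairpin2 - stem3' - segC - stem1' - ext 3'

i.e. exactly one three-way junction whose branches, in 5'->3' order, are
stem1 (toward the external loop), stem2 (toward hairpin 1) and stem3
(toward hairpin 2).  Stems are Watson-Crick complementary with GU wobbles
at a configurable rate; loop-segment lengths vary within the configured
ranges (junction segments may be empty).

Ground-truth angles are planted by a fixed smooth rule of the junction
segment lengths and stem GC fractions plus Gaussian noise, projected onto
the set of embeddable triples, and then *realized geometrically*: a toy
C4'-only PDB file is emitted in which the three closing-pair midpoints
form an equilateral triangle centred on the planted junction point and
every loop's member centroid sits exactly at its planted node position,
so the extraction pipeline recovers the planted angles to within
floating-point error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AngleSet, branch_directions

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: helical rise per base pair used to map stem length to branch length (A)
RISE_PER_BP = 2.8
#: offset added to every branch length (junction core + loop radius, A)
BRANCH_OFFSET = 4.0
#: anchor-triangle circumradius (A)
ANCHOR_RADIUS = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults define the study conditions."""

    stem_len: tuple = (2, 8)  # bp, inclusive
    loop_len: tuple = (0, 8)  # junction segment nt, inclusive
    hairpin_len: tuple = (3, 8)
    ext_len: tuple = (1, 3)  # each dangling end
    gu_prob: float = 0.1
    angle_noise_sigma: float = 5.0  # degrees
    seed: int = 0
    count: int = 1

    def __post_init__(self):
        for lo, hi in (self.stem_len, self.loop_len, self.hairpin_len, self.ext_len):
            if lo > hi or lo < 0:
                raise ValueError("invalid length range")
        if self.angle_noise_sigma < 0:
            raise ValueError("angle-noise sigma must be >= 0")


@dataclass
class SyntheticRecord:
    record_id: str
    sequence: str
    dot_bracket: str
    angles: AngleSet  # planted ground truth
    branch_lengths: tuple  # junction-to-neighbor distances (A)
    segment_lengths: tuple  # junction segments (A, B, C)
    gc_fractions: tuple  # per branch stem
    coords: dict  # residue index -> C4' position
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence / structure sampling

def _sample_stem(rng, n_bp: int, gu_prob: float):
    left, right = [], []
    for _ in range(n_bp):
        if rng.random() < gu_prob:
            a, b = ("G", "U") if rng.random() < 0.5 else ("U", "G")
        else:
            a = "AUGC"[rng.integers(4)]
            b = COMPLEMENT[a]
        left.append(a)
        right.append(b)
    return "".join(left), "".join(right[::-1])


def _sample_loop(rng, n: int) -> str:
    return "".join("AUGC"[k] for k in rng.integers(0, 4, size=n))


def sample_structure(spec: SyntheticSpec, rng) -> tuple:
    """One (sequence, dot-bracket) pair with exactly one three-way junction."""
    ri = lambda lo_hi: int(rng.integers(lo_hi[0], lo_hi[1] + 1))
    s1, s2, s3 = (ri(spec.stem_len) for _ in range(3))
    a, b, c = (ri(spec.loop_len) for _ in range(3))
    h1, h2 = ri(spec.hairpin_len), ri(spec.hairpin_len)
    e5, e3 = ri(spec.ext_len), ri(spec.ext_len)
    st1l, st1r = _sample_stem(rng, s1, spec.gu_prob)
    st2l, st2r = _sample_stem(rng, s2, spec.gu_prob)
    st3l, st3r = _sample_stem(rng, s3, spec.gu_prob)
    seq = (_sample_loop(rng, e5) + st1l + _sample_loop(rng, a)
           + st2l + _sample_loop(rng, h1) + st2r + _sample_loop(rng, b)
           + st3l + _sample_loop(rng, h2) + st3r + _sample_loop(rng, c)
           + st1r + _sample_loop(rng, e3))
    db = ("." * e5 + "(" * s1 + "." * a
          + "(" * s2 + "." * h1 + ")" * s2 + "." * b
          + "(" * s3 + "." * h2 + ")" * s3 + "." * c
          + ")" * s1 + "." * e3)
    assert len(seq) == len(db) < 500
    return seq, db


# ---------------------------------------------------------------------------
# angle rule, feasibility

def is_feasible(angles, tol: float = 1e-9) -> bool:
    """Spherical-triangle conditions for three directions in 3-space."""
    t = np.sort(np.asarray(angles, dtype=float))
    return bool(
        np.all(t > 0) and np.all(t <= 180)
        and t[2] <= t[0] + t[1] + tol
        and t.sum() <= 360.0 + tol
    )


def project_feasible(angles, center=(110.0, 110.0, 110.0), iters: int = 60) -> np.ndarray:
    """Shrink an angle triple toward a feasible center until embeddable.

    The feasible set is a convex polytope, so bisection along the segment
    to an interior point lands on the boundary facet nearest along that
    segment.  The center must be *strictly* interior: the symmetric flat
    triple (120, 120, 120) lies on the sum-360 facet itself, and pulling
    toward a boundary point would collapse any infeasible triple all the
    way onto it, erasing the noise instead of projecting it.
    """
    t = np.asarray(angles, dtype=float)
    if is_feasible(t):
        return t
    c = np.asarray(center, dtype=float)
    lo, hi = 0.0, 1.0  # fraction of the way from center to t
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if is_feasible(c + mid * (t - c)):
            lo = mid
        else:
            hi = mid
    return c + lo * (t - c)


def default_angle_rule(segment_lengths, gc_fractions) -> np.ndarray:
    """Fixed smooth map (junction segment lengths, stem GC) -> angle triple.

    Symmetric inputs give the flat (120, 120, 120) base; length asymmetry
    tilts the junction via bounded tanh terms and GC-rich neighbouring
    stems open their shared angle slightly.  The triple always sums to
    360 (a planar junction) before noise.
    """
    l = np.asarray(segment_lengths, dtype=float)
    g = np.asarray(gc_fractions, dtype=float)
    r = np.array([
        25.0 * math.tanh((l[0] - l[1]) / 4.0) + 8.0 * (g[0] + g[1] - 1.0),
        25.0 * math.tanh((l[1] - l[2]) / 4.0) + 8.0 * (g[1] + g[2] - 1.0),
        25.0 * math.tanh((l[2] - l[0]) / 4.0) + 8.0 * (g[2] + g[0] - 1.0),
    ])
    return 120.0 + (r - r.mean())


def plant_angles(rule_values, sigma: float, rng) -> AngleSet:
    """Add Gaussian noise, clip to [5, 175] and project onto the feasible set."""
    noisy = np.asarray(rule_values, dtype=float)
    if sigma > 0:
        noisy = noisy + rng.normal(0.0, sigma, size=3)
    noisy = np.clip(noisy, 5.0, 175.0)
    return AngleSet.from_array(project_feasible(noisy))


# ---------------------------------------------------------------------------
# geometric realization

def _orthonormal_plane(u_sum):
    n = u_sum if np.linalg.norm(u_sum) > 1e-6 else np.array([0.0, 0.0, 1.0])
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w1 = np.cross(n, ref)
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(n, w1)
    return w1, w2


def _spread(rng, center, count, scale=1.5):
    """``count`` points whose centroid is exactly ``center``."""
    if count == 1:
        return [np.asarray(center, dtype=float)]
    offsets = rng.normal(0.0, scale, size=(count, 3))
    offsets -= offsets.mean(axis=0)
    return [np.asarray(center) + o for o in offsets]


def realize_coordinates(seq_layout: dict, angles: AngleSet, rng) -> tuple:
    """Place C4' pseudo-atoms so that extraction recovers the planted angles.

    ``seq_layout`` maps the structural elements to index ranges (see
    :func:`make_record`).  Returns (coords, branch_lengths).
    """
    u, _ = branch_directions(angles)
    lengths = tuple(BRANCH_OFFSET + RISE_PER_BP * seq_layout[f"stem{k + 1}_bp"]
                    for k in range(3))
    targets = [lengths[k] * u[k] for k in range(3)]  # neighbour node positions
    w1, w2 = _orthonormal_plane(u.sum(axis=0))
    coords = {}

    # anchors: equilateral triangle centred on the junction point (origin);
    # its incenter is its centroid, i.e. exactly the planted junction
    anchors = []
    for k, phi in enumerate((0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)):
        anchors.append(ANCHOR_RADIUS * (math.cos(phi) * w1 + math.sin(phi) * w2))

    def place_stem(pairs, anchor, direction, closing_last: bool):
        """pairs ordered outermost->innermost along the sequence."""
        n_bp = len(pairs)
        perp = np.cross(direction, w1)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(direction, w2)
        perp /= np.linalg.norm(perp)
        for t, (i, j) in enumerate(pairs):
            # distance from the junction: closing pair sits at the anchor
            step = (n_bp - 1 - t) if closing_last else t
            mid = anchor + 2.9 * step * np.asarray(direction)
            coords[i] = mid + 0.8 * perp
            coords[j] = mid - 0.8 * perp

    place_stem(seq_layout["stem1_pairs"], anchors[0], u[0], closing_last=True)
    place_stem(seq_layout["stem2_pairs"], anchors[1], u[1], closing_last=False)
    place_stem(seq_layout["stem3_pairs"], anchors[2], u[2], closing_last=False)

    ext_idx = seq_layout["ext5"] + seq_layout["ext3"]
    for idx, p in zip(ext_idx, _spread(rng, targets[0], len(ext_idx))):
        coords[idx] = p
    for idx, p in zip(seq_layout["hp1"], _spread(rng, targets[1], len(seq_layout["hp1"]))):
        coords[idx] = p
    for idx, p in zip(seq_layout["hp2"], _spread(rng, targets[2], len(seq_layout["hp2"]))):
        coords[idx] = p
    junc_idx = seq_layout["segA"] + seq_layout["segB"] + seq_layout["segC"]
    for idx, p in zip(junc_idx, _spread(rng, np.zeros(3), max(len(junc_idx), 1))):
        coords[idx] = p
    return coords, lengths


def make_record(spec: SyntheticSpec, rng, record_id: str) -> SyntheticRecord:
    """Sample one complete record: structure, planted angles, coordinates."""
    from .features import stem_edge_features
    from .secstruct import build_tree_graph, find_three_way_junctions, parse_dot_bracket

    seq, db = sample_structure(spec, rng)
    ss = parse_dot_bracket(db, seq)
    tree = build_tree_graph(ss)
    (junction,) = find_three_way_junctions(tree)
    jm = tree.motifs[junction.node_id]
    seg_lengths = jm.segment_lengths
    stems = {s.stem_id: s for s in tree.stems}
    gcs = tuple(float(stem_edge_features(stems[sid], seq)[1])
                for sid in junction.branches)
    angles = plant_angles(default_angle_rule(seg_lengths, gcs),
                          spec.angle_noise_sigma, rng)

    layout = {}
    for k, sid in enumerate(junction.branches):
        layout[f"stem{k + 1}_bp"] = stems[sid].length_bp
        layout[f"stem{k + 1}_pairs"] = list(stems[sid].pairs)
    ext = next(m for m in tree.motifs if m.kind == "E")
    layout["ext5"] = list(ext.segments[0])
    layout["ext3"] = list(ext.segments[1])
    layout["segA"], layout["segB"], layout["segC"] = (list(s) for s in jm.segments)
    hp_nodes = [nb for nb in junction.neighbors[1:]]
    layout["hp1"] = list(tree.motifs[hp_nodes[0]].segments[0])
    layout["hp2"] = list(tree.motifs[hp_nodes[1]].segments[0])

    coords, _ = realize_coordinates(layout, angles, rng)
    # quantize to the PDB coordinate grid (0.001 A) and store the exact
    # geometry of the quantized coordinates as ground truth, so that the
    # emitted file reproduces the planted values bit-for-bit
    coords = {k: np.round(v, 3) for k, v in coords.items()}
    from .geometry import extract_chain_geometry

    (geom,) = extract_chain_geometry(ss, coords)
    return SyntheticRecord(
        record_id=record_id, sequence=seq, dot_bracket=db, angles=geom["angles"],
        branch_lengths=geom["branch_lengths"], segment_lengths=tuple(seg_lengths),
        gc_fractions=gcs, coords=coords,
    )


def generate_records(spec: SyntheticSpec, seed=None) -> list:
    """``spec.count`` in-memory records, deterministic from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return [make_record(spec, rng, f"syn{k:04d}") for k in range(spec.count)]


# ---------------------------------------------------------------------------
# file output

def emit_structure_file(record: SyntheticRecord, path) -> None:
    """Write a minimal C4'-only PDB file (chain A, 1-based residues)."""
    import gemmi

    st = gemmi.Structure()
    st.name = record.record_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for idx, base in enumerate(record.sequence):
        res = gemmi.Residue()
        res.name = base if base != "N" else "UNK"
        res.seqid = gemmi.SeqId(idx + 1, " ")
        atom = gemmi.Atom()
        atom.name = "C4'"
        atom.element = gemmi.Element("C")
        x, y, z = record.coords[idx]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def generate_dataset(spec: SyntheticSpec, outdir, seed=None):
    """Write FASTA / dot-bracket / PDB files plus a manifest CSV.

    Returns ``(records, manifest DataFrame)``; regeneration with the same
    seed is bit-identical.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    records = generate_records(spec, seed=seed)
    rows = []
    for r in records:
        fasta = f"{r.record_id}.fasta"
        dbn = f"{r.record_id}.dbn"
        pdb = f"{r.record_id}.pdb"
        for name in (fasta, dbn, pdb):
            if (outdir / name).exists():
                raise FileExistsError(f"{outdir / name} already exists")
        (outdir / fasta).write_text(f">{r.record_id}\n{r.sequence}\n")
        (outdir / dbn).write_text(f">{r.record_id}\n{r.sequence}\n{r.dot_bracket}\n")
        emit_structure_file(r, outdir / pdb)
        r.paths = {"fasta": fasta, "dbn": dbn, "pdb": pdb}
        rows.append({
            "id": r.record_id, "fasta": fasta, "dbn": dbn, "pdb": pdb, "chain": "A",
            "theta1": r.angles.theta1, "theta2": r.angles.theta2,
            "theta3": r.angles.theta3,
            "L1": r.branch_lengths[0], "L2": r.branch_lengths[1],
            "L3": r.branch_lengths[2],
        })
    df = pd.DataFrame(rows)
    df.to_csv(manifest_path, index=False)
    return records, df
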