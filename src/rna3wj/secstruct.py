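"""Secondary-structure parsing and coarse-grained tree-graph construction.

An RNA secondary structure in dot-bracket notation is decomposed into
helical stems (maximal runs of stacked nested base pairs) and loop motifs
(hairpin H, bulge B, internal I, multibranch M, external E).  Loops become
the nodes and stems the edges of a planar *tree graph*; a three-way
junction is a degree-3 multibranch node whose three branches are ordered
5'->3' by the first nucleotide index of each stem.

Indices are 0-based throughout the API; user-facing reports are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import StructureParseError, UnsupportedTopologyError

#: bracket families accepted in dot-bracket strings; "()" encodes the nested
#: (tree-forming) layer, the others encode pseudoknotted pairs.
BRACKET_FAMILIES = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in BRACKET_FAMILIES.items()}
VALID_BASES = set("AUGCN")


@dataclass(frozen=True)
class SecondaryStructure:
    """Sequence plus pairing maps.

    ``nested_pairs`` is the non-crossing layer used for tree construction;
    ``pseudoknot_pairs`` holds crossing pairs, which the tree graph ignores
    but the nucleotide graph represents as a distinct edge type.
    """

    sequence: str
    nested_pairs: frozenset
    pseudoknot_pairs: frozenset = frozenset()

    def __post_init__(self):
        n = len(self.sequence)
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise StructureParseError(f"invalid bases in sequence: {sorted(bad)}")
        seen = set()
        for (i, j) in list(self.nested_pairs) + list(self.pseudoknot_pairs):
            if not (0 <= i < j < n):
                raise StructureParseError(f"pair ({i},{j}) out of range for length {n}")
            for k in (i, j):
                if k in seen:
                    raise StructureParseError(f"index {k} appears in more than one pair")
                seen.add(k)
        _check_non_crossing(self.nested_pairs)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner(self) -> dict:
        """index -> nested-pair partner."""
        out = {}
        for i, j in self.nested_pairs:
            out[i] = j
            out[j] = i
        return out

    def pseudoknot_indices(self) -> set:
        out = set()
        for i, j in self.pseudoknot_pairs:
            out.add(i)
            out.add(j)
        return out


def _check_non_crossing(pairs) -> None:
    opens = sorted(pairs)
    stack = []
    for i, j in opens:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (j < stack[-1][1]):
            raise StructureParseError(
                f"nested pairs cross: ({stack[-1][0]},{stack[-1][1]}) and ({i},{j})"
            )
        stack.append((i, j))


@dataclass(frozen=True)
class Stem:
    """Maximal run of stacked nested pairs; consecutive pairs are (i+1, j-1)."""

    stem_id: int
    pairs: tuple  # ordered outermost -> innermost

    @property
    def length_bp(self) -> int:
        return len(self.pairs)

    @property
    def outer_pair(self):
        return self.pairs[0]

    @property
    def inner_pair(self):
        return self.pairs[-1]

    @property
    def first_index(self) -> int:
        """Smallest nucleotide index of the stem (5'-most position)."""
        return self.pairs[0][0]

    def indices(self) -> set:
        return {k for p in self.pairs for k in p}


@dataclass(frozen=True)
class Motif:
    """A loop motif: node of the tree graph.

    ``segments`` are ordered 5'->3' tuples of unpaired nucleotide indices
    (possibly empty); ``incident_stems`` are stem ids ordered by each stem's
    first nucleotide index.
    """

    motif_id: int
    kind: str  # one of H B I M E X
    segments: tuple  # tuple of tuples of indices
    incident_stems: tuple

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_lengths(self) -> tuple:
        return tuple(len(s) for s in self.segments)

    def member_indices(self) -> tuple:
        return tuple(k for seg in self.segments for k in seg)


@dataclass
class TreeGraph:
    """Loops as nodes, stems as edges; a tree for pseudoknot-free input."""

    motifs: list
    stems: list
    edges: list  # (motif_id_outer, motif_id_inner, stem_id)
    labels: str  # per-nucleotide motif label, len == sequence length

    def __post_init__(self):
        g = nx.Graph()
        g.add_nodes_from(m.motif_id for m in self.motifs)
        for u, v, s in self.edges:
            g.add_edge(u, v, stem=s)
        if len(self.motifs) and not nx.is_tree(g):
            raise UnsupportedTopologyError(
                "loop/stem graph is not a tree (disconnected or cyclic)"
            )
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def degree(self, motif_id: int) -> int:
        return self._graph.degree[motif_id]

    def neighbor_via(self, motif_id: int, stem_id: int) -> int:
        for u, v, s in self.edges:
            if s == stem_id:
                if u == motif_id:
                    return v
                if v == motif_id:
                    return u
        raise KeyError(f"stem {stem_id} not incident to motif {motif_id}")

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "id": m.motif_id,
                    "kind": m.kind,
                    "segments": [[i + 1 for i in seg] for seg in m.segments],
                }
                for m in self.motifs
            ],
            "edges": [
                {
                    "stem": s,
                    "between": [u, v],
                    "pairs": [[i + 1, j + 1] for i, j in self.stems[s].pairs],
                }
                for u, v, s in self.edges
            ],
        }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class ThreeWayJunction:
    """Degree-3 multibranch node with branches ordered 5'->3'.

    ``closing_pairs[k]`` is the base pair of branch-k's stem nearest the
    junction; ``neighbors[k]`` the tree node at the far end of branch k.
    """

    node_id: int
    branches: tuple  # stem ids (Branch 1, 2, 3)
    closing_pairs: tuple
    neighbors: tuple


def parse_dot_bracket(db: str, seq: str) -> SecondaryStructure:
    """Parse a dot-bracket string against its sequence.

    Round parentheses populate ``nested_pairs``; the other bracket families
    ("[]", "{}", "<>") populate ``pseudoknot_pairs``.
    """
    if len(db) != len(seq):
        raise StructureParseError(
            f"structure length {len(db)} != sequence length {len(seq)}"
        )
    stacks = {o: [] for o in BRACKET_FAMILIES}
    nested, pk = set(), set()
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in BRACKET_FAMILIES:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise StructureParseError(
                    f"unbalanced '{ch}' at position {pos + 1}: no matching '{opener}'"
                )
            i = stacks[opener].pop()
            (nested if opener == "(" else pk).add((i, pos))
        else:
            raise StructureParseError(f"invalid character {ch!r} at position {pos + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unbalanced '{opener}' at position {stack[-1] + 1}: never closed"
            )
    return SecondaryStructure(seq.upper(), frozenset(nested), frozenset(pk))


_PK_FAMILIES = [("[", "]"), ("{", "}"), ("<", ">")]


def render_dot_bracket(ss: SecondaryStructure) -> str:
    """Inverse of :func:`parse_dot_bracket` (pseudoknot pairs are greedily
    assigned to the '[]', '{}', '<>' families so that no family crosses
    itself)."""
    out = ["."] * ss.length
    for i, j in ss.nested_pairs:
        out[i], out[j] = "(", ")"
    groups = [[] for _ in _PK_FAMILIES]
    for i, j in sorted(ss.pseudoknot_pairs):
        for g, (o, c) in zip(groups, _PK_FAMILIES):
            if all(not (a < i < b < j or i < a < j < b) for a, b in g):
                g.append((i, j))
                out[i], out[j] = o, c
                break
        else:
            raise StructureParseError(
                "pseudoknot pairs need more than three mutually crossing families"
            )
    return "".join(out)


def find_stems(ss: SecondaryStructure) -> list:
    """Partition nested pairs into maximal stacked runs, ordered by 5' index."""
    pairs = sorted(ss.nested_pairs)
    stems, run = [], []
    for p in pairs:
        if run and p == (run[-1][0] + 1, run[-1][1] - 1):
            run.append(p)
        else:
            if run:
                stems.append(run)
            run = [p]
    if run:
        stems.append(run)
    stems.sort(key=lambda r: r[0][0])
    return [Stem(k, tuple(r)) for k, r in enumerate(stems)]


def _stem_forest(stems):
    """parent stem id for each stem (None for top level), by interval nesting."""
    parent = {}
    stack = []
    for s in sorted(stems, key=lambda s: s.outer_pair[0]):
        while stack and stack[-1].outer_pair[1] < s.outer_pair[0]:
            stack.pop()
        parent[s.stem_id] = stack[-1].stem_id if stack else None
        stack.append(s)
    return parent


def classify_loops(ss: SecondaryStructure, stems: list):
    """Enumerate loop motifs and label every nucleotide.

    Returns ``(motifs, labels)`` where ``labels`` is a string over
    {S,H,B,I,M,E,X}.  Stem nucleotides are S; nucleotides paired only in
    pseudoknots are X and excluded from loop segments; everything else
    belongs to exactly one loop motif and carries its kind letter.

    Raises :class:`UnsupportedTopologyError` for junctions with more than
    three branches.
    """
    n = ss.length
    labels = ["X"] * n
    pk_idx = ss.pseudoknot_indices()
    for s in stems:
        for k in s.indices():
            labels[k] = "S"

    parent = _stem_forest(stems)
    children = {s.stem_id: [] for s in stems}
    roots = []
    for s in sorted(stems, key=lambda s: s.outer_pair[0]):
        if parent[s.stem_id] is None:
            roots.append(s)
        else:
            children[parent[s.stem_id]].append(s)

    def run(lo, hi):
        """unpaired (non-pk) indices in the open interval [lo, hi]."""
        return tuple(k for k in range(lo, hi + 1) if labels[k] == "X" and k not in pk_idx)

    motifs = []

    def add(kind, segments, incident):
        m = Motif(len(motifs), kind, tuple(segments), tuple(incident))
        motifs.append(m)
        for seg in segments:
            for k in seg:
                labels[k] = kind
        return m

    # external loop: always present, segments around/between top-level stems
    ext_segments = []
    bounds = [-1] + [b for s in roots for b in (s.outer_pair[0], s.outer_pair[1])] + [n]
    for a, b in zip(bounds[::2], bounds[1::2]):
        ext_segments.append(run(a + 1, b - 1))
    add("E", ext_segments, [s.stem_id for s in roots])

    for t in sorted(stems, key=lambda s: s.outer_pair[0]):
        ic, jc = t.inner_pair
        kids = children[t.stem_id]
        cuts = [ic] + [b for c in kids for b in (c.outer_pair[0], c.outer_pair[1])] + [jc]
        segs = [run(a + 1, b - 1) for a, b in zip(cuts[::2], cuts[1::2])]
        incident = [t.stem_id] + [c.stem_id for c in kids]
        if not kids:
            add("H", segs, incident)
        elif len(kids) == 1:
            if segs[0] and segs[1]:
                add("I", segs, incident)
            else:
                # bulge: keep only the (single) non-empty segment
                add("B", [s for s in segs if s] or [()], incident)
        elif len(kids) == 2:
            add("M", segs, incident)
        else:
            raise UnsupportedTopologyError(
                f"junction with {len(kids) + 1} branches at stem {t.stem_id} "
                "(only three-way junctions are supported)"
            )
    return motifs, "".join(labels)


def build_tree_graph(ss: SecondaryStructure) -> TreeGraph:
    """Build the coarse-grained tree graph (loops as nodes, stems as edges).

    Pseudoknot pairs are excluded: crossing topologies cannot be represented
    by a planar tree.
    """
    stems = find_stems(ss)
    motifs, labels = classify_loops(ss, stems)
    parent = _stem_forest(stems)
    # motif interior to each stem: the motif whose first incident stem is it
    interior = {}
    for m in motifs:
        if m.kind != "E" and m.incident_stems:
            interior[m.incident_stems[0]] = m.motif_id
    ext_id = next(m.motif_id for m in motifs if m.kind == "E")
    edges = []
    for s in stems:
        outer = ext_id if parent[s.stem_id] is None else interior[parent[s.stem_id]]
        edges.append((outer, interior[s.stem_id], s.stem_id))
    return TreeGraph(motifs, stems, edges, labels)


def find_three_way_junctions(tree: TreeGraph) -> list:
    """All degree-3 multibranch nodes with 5'->3'-ordered branches."""
    out = []
    by_id = {s.stem_id: s for s in tree.stems}
    for m in tree.motifs:
        if m.kind != "M" or tree.degree(m.motif_id) != 3:
            continue
        branches = tuple(sorted(m.incident_stems, key=lambda sid: by_id[sid].first_index))
        closing, neighbors = [], []
        for sid in branches:
            stem = by_id[sid]
            inner_id = None
            for u, v, s in tree.edges:
                if s == sid:
                    inner_id = v
                    break
            # pair nearest the junction: inner pair if the junction sits
            # inside this stem, outer pair if the stem opens away from it
            closing.append(stem.inner_pair if inner_id == m.motif_id else stem.outer_pair)
            neighbors.append(tree.neighbor_via(m.motif_id, sid))
        out.append(ThreeWayJunction(m.motif_id, branches, tuple(closing), tuple(neighbors)))
    return out


# ---------------------------------------------------------------------------
# file input

def read_fasta(path) -> str:
    """First record of a FASTA file, as an uppercase RNA sequence (T -> U)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper().replace("T", "U")


def read_vienna(path):
    """Vienna dot-bracket file: optional '>' header, sequence line, structure line.

    Returns a parsed :class:`SecondaryStructure`.
    """
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureParseError(f"{path}: expected sequence and structure lines")
    return parse_dot_bracket(lines[1], lines[0])
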