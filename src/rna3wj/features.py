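"""Feature construction for both graph resolutions.

Fine-grained nucleotide graph: one node per nucleotide with an 11-dim
feature vector (4-dim base one-hot A/U/G/C, all-zero for N, plus 7-dim
motif-label one-hot S/H/B/I/M/E/X); undirected edges typed backbone /
nested pair / pseudoknot as a 3-dim one-hot.

Coarse-grained tree graph: each loop node carries a 24-dim vector of eight
3-padded feature groups derived from its loop-segment lengths and sequence
(raw lengths, pairwise minima, ascending-sorted lengths, pairwise absolute
differences, pairwise ratios, length fractions, max consecutive A/U run,
max consecutive A run); each stem edge carries (stem length in base pairs,
GC fraction, AU fraction, GU fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UnsupportedTopologyError
from .secstruct import Motif, SecondaryStructure, Stem, TreeGraph

BASE_INDEX = {"A": 0, "U": 1, "G": 2, "C": 3}
MOTIF_LABELS = "SHBIMEX"
EDGE_TYPES = ("backbone", "pair", "pseudoknot")

#: Table-order names of the eight tree-node feature groups; each occupies
#: three consecutive columns of the 24-dim node vector.
FEATURE_GROUPS = (
    "segment_lengths",
    "pairwise_min",
    "sorted_lengths",
    "pairwise_abs_diff",
    "pairwise_ratio",
    "length_fraction",
    "max_au_run",
    "max_a_run",
)

#: Human-readable layout fingerprint; stored in checkpoints and verified at
#: load/predict time, because the column order is part of the model contract.
FEATURE_FINGERPRINT = (
    "node11=base4(AUGC)+motif7(SHBIMEX);edge3=backbone,pair,pseudoknot;"
    "tree24=" + ",".join(FEATURE_GROUPS) + ";stem4=Lstem,fGC,fAU,fGU"
)

LEN_ONLY_DIM = 3  # length-only ablation keeps just the raw-lengths group
TREE_NODE_DIM = 24
TREE_EDGE_DIM = 4
NUC_NODE_DIM = 11

_PAIR_ORDER = ((0, 1), (0, 2), (1, 2))


@dataclass
class NucleotideGraph:
    """Fine-grained graph over nucleotides (edges stored once, undirected)."""

    node_features: np.ndarray  # (n, 11)
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_types: np.ndarray  # (E, 3) one-hot

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def build_nucleotide_graph(ss: SecondaryStructure, labels: str) -> NucleotideGraph:
    """Assemble the nucleotide graph from a structure and its motif labels."""
    n = ss.length
    if len(labels) != n:
        raise ContractError("label string length does not match the sequence")
    x = np.zeros((n, NUC_NODE_DIM))
    for k, (base, lab) in enumerate(zip(ss.sequence, labels)):
        if base in BASE_INDEX:  # N keeps an all-zero base block
            x[k, BASE_INDEX[base]] = 1.0
        x[k, 4 + MOTIF_LABELS.index(lab)] = 1.0
    src, dst, types = [], [], []

    def add(i, j, t):
        src.append(i)
        dst.append(j)
        onehot = np.zeros(3)
        onehot[t] = 1.0
        types.append(onehot)

    for i in range(n - 1):
        add(i, i + 1, 0)
    for i, j in sorted(ss.nested_pairs):
        add(i, j, 1)
    for i, j in sorted(ss.pseudoknot_pairs):
        add(i, j, 2)
    return NucleotideGraph(
        x,
        np.array(src, dtype=np.int64),
        np.array(dst, dtype=np.int64),
        np.array(types) if types else np.zeros((0, 3)),
    )


def _max_run(segment_seq: str, alphabet: str) -> int:
    best = cur = 0
    for ch in segment_seq:
        cur = cur + 1 if ch in alphabet else 0
        best = max(best, cur)
    return best


def _pad3(values) -> list:
    out = list(values)[:3] + [0.0] * (3 - len(values))
    return [float(v) for v in out]


def tree_node_features(motif: Motif, seq: str) -> np.ndarray:
    """24-dim tree-node feature vector (eight groups, each padded to 3).

    Sorting applies to the real segment lengths only, before padding; the
    ratio denominator is zero-guarded as max(|Lj|, 1); pairwise groups use
    the (1,2), (1,3), (2,3) enumeration order.
    """
    M = motif.n_segments
    if M > 3:
        raise UnsupportedTopologyError(
            f"motif with {M} loop segments exceeds the 3-segment feature capacity"
        )
    lengths = [float(len(s)) for s in motif.segments]
    seqs = ["".join(seq[k] for k in s) for s in motif.segments]
    total = sum(lengths)
    pairs = [(i, j) for i, j in _PAIR_ORDER if j < M]
    groups = [
        _pad3(lengths),
        _pad3([min(lengths[i], lengths[j]) for i, j in pairs]),
        _pad3(sorted(lengths)),
        _pad3([abs(lengths[i] - lengths[j]) for i, j in pairs]),
        _pad3([lengths[i] / max(lengths[j], 1.0) for i, j in pairs]),
        _pad3([l / total for l in lengths] if total > 0 else [0.0] * M),
        _pad3([_max_run(s, "AU") for s in seqs]),
        _pad3([_max_run(s, "A") for s in seqs]),
    ]
    return np.array([v for g in groups for v in g])


def stem_edge_features(stem: Stem, seq: str) -> np.ndarray:
    """(Lstem, fGC, fAU, fGU); unordered pair counting (GC and CG alike)."""
    counts = {"GC": 0, "AU": 0, "GU": 0}
    for i, j in stem.pairs:
        key = "".join(sorted((seq[i], seq[j])))  # e.g. CG -> "CG"
        if key in ("CG", "GC"):
            counts["GC"] += 1
        elif key in ("AU", "UA"):
            counts["AU"] += 1
        elif key in ("GU", "UG"):
            counts["GU"] += 1
    L = stem.length_bp
    return np.array([float(L), counts["GC"] / L, counts["AU"] / L, counts["GU"] / L])


@dataclass
class FeaturizedChain:
    """Everything the model needs for one chain, with deterministic ordering."""

    ss: SecondaryStructure
    tree: TreeGraph
    nuc_graph: NucleotideGraph
    tree_node_x: np.ndarray  # (T, 24), row t = motif_id t
    tree_edge_x: np.ndarray  # (T-1, 4), row e = e-th edge of tree.edges
    tree_edge_src: np.ndarray
    tree_edge_dst: np.ndarray
    loop_member_nt: np.ndarray  # nucleotide indices that belong to loop nodes
    loop_member_node: np.ndarray  # tree node id for each entry of loop_member_nt
    stem_member_nt: np.ndarray
    stem_member_edge: np.ndarray  # tree edge row for each stem nucleotide
    junction_node_ids: list

    @property
    def n_tree_nodes(self) -> int:
        return self.tree_node_x.shape[0]


def featurize_chain(ss: SecondaryStructure, labels: str, tree: TreeGraph) -> FeaturizedChain:
    """Assemble both graph resolutions and the nucleotide->tree membership map.

    Loop nucleotides map to their motif node, stem nucleotides to their stem
    edge; pseudoknot-only (X-labeled) nucleotides belong to neither.
    """
    from .secstruct import find_three_way_junctions

    if tree.labels != labels:
        raise ContractError("labels do not match the tree graph's labels")
    nuc = build_nucleotide_graph(ss, labels)
    node_x = np.vstack([tree_node_features(m, ss.sequence) for m in tree.motifs])
    edge_rows = []
    src, dst = [], []
    stem_to_edge = {}
    for row, (u, v, sid) in enumerate(tree.edges):
        edge_rows.append(stem_edge_features(tree.stems[sid], ss.sequence))
        src.append(u)
        dst.append(v)
        stem_to_edge[sid] = row
    loop_nt, loop_node = [], []
    for m in tree.motifs:
        for k in m.member_indices():
            loop_nt.append(k)
            loop_node.append(m.motif_id)
    stem_nt, stem_edge = [], []
    for s in tree.stems:
        for k in sorted(s.indices()):
            stem_nt.append(k)
            stem_edge.append(stem_to_edge[s.stem_id])
    return FeaturizedChain(
        ss=ss,
        tree=tree,
        nuc_graph=nuc,
        tree_node_x=node_x,
        tree_edge_x=np.vstack(edge_rows) if edge_rows else np.zeros((0, TREE_EDGE_DIM)),
        tree_edge_src=np.array(src, dtype=np.int64),
        tree_edge_dst=np.array(dst, dtype=np.int64),
        loop_member_nt=np.array(loop_nt, dtype=np.int64),
        loop_member_node=np.array(loop_node, dtype=np.int64),
        stem_member_nt=np.array(stem_nt, dtype=np.int64),
        stem_member_edge=np.array(stem_edge, dtype=np.int64),
        junction_node_ids=[j.node_id for j in find_three_way_junctions(tree)],
    )


def featurize(ss: SecondaryStructure) -> FeaturizedChain:
    """Convenience: build tree graph + features straight from a structure."""
    from .secstruct import build_tree_graph

    tree = build_tree_graph(ss)
    return featurize_chain(ss, tree.labels, tree)
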