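# Methods

## Problem and representation

An RNA three-way junction (3WJ) is a loop at which exactly three helical
stems converge. Given only the primary sequence and a pseudoknot-free
secondary structure in dot-bracket notation, the package predicts the
three inter-branch angles θ1 (Branches 1–2), θ2 (2–3) and θ3 (3–1), each
in (0°, 180°], where branches are numbered 5′→3′ by the first nucleotide
index of their stems.

Two graph resolutions are built from the same structure:

* **Nucleotide graph** — one node per nucleotide with an 11-dim one-hot
  feature (base A/U/G/C; motif label S/H/B/I/M/E/X), and undirected edges
  typed backbone / nested pair / pseudoknot (3-dim one-hot). Pseudoknot
  pairs cannot be represented in a planar tree, so they appear only here.
* **Tree graph** — loops as nodes, stems as edges. Each node carries a
  24-dim vector of eight 3-padded groups derived from its loop-segment
  lengths and sequence: raw lengths (5′→3′), pairwise minima, lengths
  sorted ascending, pairwise absolute differences, pairwise ratios,
  fractions of the total loop length, maximum consecutive A/U run and
  maximum consecutive A run. Each stem edge carries (L_stem, f_GC, f_AU,
  f_GU).

Conventions that the tables leave open, fixed here and recorded in the
checkpoint fingerprint: sorting applies to the real segment lengths only
and padding zeros are appended afterwards (padding is a vectorization
device, not data); ratio denominators are zero-guarded as max(|Lj|, 1)
because empty junction segments are common; pairwise groups enumerate
(1,2), (1,3), (2,3); an N base has an all-zero base block; external loops
are featurized like any other loop.

## Ground-truth geometry

C4′ atoms are used as conformationally stable backbone anchors. A
non-junction loop node's coordinate is the centroid of its members' C4′
atoms. A junction node's coordinate is the **incenter** of the triangle
formed by the three branch anchors, each anchor being the midpoint of the
two C4′ atoms of that branch's closing base pair (the stem pair nearest
the junction). Branch direction k is the vector from the junction
coordinate to the coordinate of the adjacent tree node reached via branch
k; angles are arccos of clipped cosines. The alternative convention
(anchor midpoints as endpoints) is available via
``compute_inter_branch_angles(..., branch_endpoint="anchor")``.

Degenerate cases: a collinear anchor triangle (area < 1e−6 Å²) falls back
to the anchor centroid with a warning; a zero-length branch vector
(< 1e−9 Å) is an error; residues without a C4′ atom are skipped, and a
junction whose node coordinates cannot all be resolved is skipped with a
logged reason.

## Skeleton reconstruction and RMSD

A junction is abstracted as a **rigid star**: center + three endpoints.
Reconstruction places u1 = +x, u2 in the xy-plane at θ1, and solves
u3·u1 = cos θ3, u3·u2 = cos θ2 with out-of-plane component
+√(max(0, 1−x²−y²)). When the spherical-triangle constraints
(θi ≤ θj + θk, Σθ ≤ 360°) are violated, u3 is embedded in-plane at the
nearest attainable boundary (θ3 → θ1 ± θ2), the star is flagged
infeasible, and realized angles are reported rather than failing.
θ1 within 1e−7 rad of 0/180° is perturbed to keep the frame well defined.

Skeleton RMSD superposes the 4 matched points by Kabsch (proper rotations
+ translation; `scipy` `Rotation.align_vectors`) and takes the minimum
over the two chirality choices, because an angle triple does not
determine handedness. Native branch lengths are the Euclidean distances
from the native junction coordinate to its neighbor node coordinates (3D
tree-edge lengths), keeping reconstruction commensurate with the
native-abstracted star.

## Model

* **Nucleotide encoder** — one 2-head attention message-passing layer
  (TransformerConv-style: per-edge keys/values augmented with the edge
  type embedding, scaled dot-product attention over incoming edges, plus
  a root/skip transform), ReLU, dropout. Per-nucleotide embeddings are
  mean-pooled over each tree node's loop members (stem nucleotides
  contribute through message passing only; a memberless node gets the
  zero vector).
* **Tree encoders** — independent affine+ReLU maps of the 24-dim node
  and 4-dim edge features into the shared hidden space.
* **Gated fusion** — h = z·h_nucleotide + (1−z)·h_tree with
  z = sigmoid(affine([h_nucleotide ⊕ h_tree])). The gate is per-dimension
  by default ("dynamically modulates" implies input dependence);
  ``gate_mode="scalar"`` gives a single coefficient per node.
* **Junction head** — LayerNorm, one 2-head graph attention pass over the
  *tree* graph (GATv2-style scoring with stem-edge embeddings and
  self-loops), residual add, then an MLP mapping each junction node to
  the 6-dim encoding [sin θ1, cos θ1, sin θ2, cos θ2, sin θ3, cos θ3].
* **Decoding** — θ = |atan2(s, c)|, scale-invariant per pair; ground
  truth lies in (0°, 180°] so the sign carries no information.
* **Loss** — mean over valid junctions of Σ_k ‖ŷ_k − y_k‖² on the unit
  circle, with masking for junction-less outputs.

Ablation variants (exactly one active): ``no_tree`` (head consumes pooled
nucleotide embeddings only, zero edge embeddings), ``no_nucleotide``
(h = h_tree), ``gcn_message_passing`` (both attention aggregations
replaced by degree-normalized means), ``concat_fusion`` (concatenation +
affine re-projection), ``len_only_features`` (tree node features truncated
to the raw-length group).

The network is implemented on a small reverse-mode autodiff core
(`autodiff.py`) written for this package: broadcasting arithmetic,
matmul, gather/segment-sum, segment softmax and layer norm, verified
against finite differences in the test suite.

### Training

AdamW (decoupled weight decay) with defaults hidden=64, dropout=0.2,
lr=1e−3, weight decay=1e−2, plateau LR decay (factor 0.5, patience 25 on
validation loss), max 500 epochs, early stop patience 60, batch size 64
(one chain per graph; batches are disjoint unions). A single integer seed
drives weight init, the train/validation split (10% of chains by
default), shuffling and dropout; training is exactly reproducible.
Cross-validation splits at the **chain** level so junctions of one
molecule never straddle folds. The weights reported are those of the
best monitored epoch.

The scheduler patience values deserve a note: the validation loss of a
small-chain dataset is noisy from epoch to epoch, and a short plateau
patience halves the learning rate so quickly that optimization freezes
far from convergence. Patience 25 (with early stop 60 so training can
recover after a decay) lets the reference synthetic task train to its
loss plateau; both remain ordinary config fields.

## Synthetic data

The generator emulates the curated data regime — single-3WJ chains
shorter than 500 nt — with the layout ext5′–stem1–segA–stem2–hairpin1–
stem2′–segB–stem3–hairpin2–stem3′–segC–stem1′–ext3′. Defaults: stems 2–8
bp, junction segments 0–8 nt, hairpins 3–8 nt, dangling ends 1–3 nt, GU
wobble probability 0.1, angle noise σ = 5° (the same order as the spread
of native junction angles).

The planted rule is fixed so recovery results are comparable: with
junction segment lengths (lA, lB, lC) and branch-stem GC fractions
(g1, g2, g3),

    r1 = 25·tanh((lA−lB)/4) + 8·(g1+g2−1)   (r2, r3 cyclically)
    θk = 120 + (rk − mean(r))

The symmetric base is (120°, 120°, 120°) and the pre-noise triple always
sums to 360° (a planar junction). Gaussian noise (σ) is added, angles are
clipped to [5°, 175°] and, when the noise pushes the triple outside the
feasible polytope, projected back by bisection toward the strictly
interior point (110, 110, 110) — the projection must not target the
symmetric flat triple itself, which lies on the sum-360 facet.

Geometric realization: branch directions are taken from the skeleton
reconstruction of the planted triple; branch length k is 4.0 + 2.8·(stem
k base pairs) Å (A-form-like rise); the three closing-pair midpoints form
an equilateral triangle (circumradius 2 Å) centred on the junction point,
whose incenter is therefore exactly the planted junction coordinate;
every loop's members are scattered with their centroid exactly at the
planted node position; stems are traced as straight runs. Coordinates are
quantized to the PDB 0.001 Å grid and the stored ground truth is the
exact geometry of the quantized coordinates, so extraction from the
emitted file reproduces the stored angles bit-for-bit.

What the generator does **not** emulate: physically realistic A-form
helices, coaxial stacking, non-canonical pairs, tertiary contacts, and
multi-junction chains. Passing recovery tests therefore demonstrates the
pipeline's internal consistency and the model's capacity to learn smooth
sequence/topology→geometry maps at realistic sizes — not performance on
experimental structures.

## Recovery benchmark

The parameter-recovery experiment trains on 300 synthetic chains and
evaluates on 60 held-out chains (joint ACC at τ = 20°), averaged over 3
seeds, with the full model compared against both single-resolution
ablations, at the default configuration with a 250-epoch budget (the
loss plateaus well before that on this task). Under the planted rule
both resolutions see correlated signal — the tree features are close to
sufficient for the rule — so the orderings mirror, rather than
reproduce, the relative standings observed on experimental data, and the
tree-only ablation is expected to run the full model close.

## Metrics

ACC(τ) is reported per angle, overall (the 1/(3N) double sum) and
jointly; angular error is the plain absolute difference (no circular
wrap — a naive circular distance would differ at the 0/180 boundary).
MAE is the mean of the three absolute deviations of one junction.
Reported accuracies are rounded to 3 decimals in CSV/JSON reports.
Permutation importance shuffles one named tree-node feature group across
junction samples and reports the mean drop in joint ACC(20°).

## Known limitations

* Junctions with ≥4 branches are rejected, matching the data regime.
* Single-closing-pair anchors are sensitive to local distortions;
  multi-pair helical-axis fitting is out of scope.
* The GNN runs one message-passing layer per resolution; deep stacks and
  GPU-scale training are out of scope.
* Curation of experimental datasets (structure download, annotation,
  redundancy clustering) is not part of the package.
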