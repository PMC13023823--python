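"""Dual-resolution attention GNN for inter-branch angle regression.

The network blends two views of a chain:

* a fine-grained **nucleotide graph** encoded by one two-head
  attention-based message-passing layer, mean-pooled per loop over each
  tree node's member nucleotides;
* a coarse-grained **tree graph** whose 24-dim node and 4-dim edge feature
  vectors pass through independent affine encoders.

The two per-tree-node representations are combined by a learned gate
``h = z * h_nucleotide + (1 - z) * h_tree`` with ``z = sigmoid(affine([h_n
, h_t]))``, refined by LayerNorm -> two-head graph attention over the tree
-> residual, and read out at each three-way-junction node through an MLP
producing the 6-dim ``[sin t1, cos t1, sin t2, cos t2, sin t3, cos t3]``
encoding.  Training minimizes the mean (over valid junctions) of the
summed squared distances between predicted and ground-truth unit-circle
points, with AdamW, plateau learning-rate decay and early stopping.

The public surface follows the Model/Results convention:
``JunctionAngleModel(dataset, config).fit()`` returns a
:class:`JunctionAngleResults` carrying the trained weights, history,
``predict``/``evaluate``/``summary`` and exact save/load.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features as F
from .autodiff import AdamW, ReduceLROnPlateau, Tensor, concat, gather_rows, segment_sum
from .errors import ContractError, Rna3wjError, TrainingDivergedError
from .features import FEATURE_FINGERPRINT, FeaturizedChain, featurize
from .geometry import AngleSet
from .layers import GATConv, LayerNorm, Linear, TransformerConv, dropout
from .secstruct import SecondaryStructure

VARIANTS = ("full", "no_tree", "no_nucleotide", "gcn_message_passing",
            "concat_fusion", "len_only_features")


# ---------------------------------------------------------------------------
# angle <-> unit-circle encoding

def encode_angles(angles) -> np.ndarray:
    """[sin t1, cos t1, sin t2, cos t2, sin t3, cos t3] for a triple in degrees."""
    a = angles.as_array() if isinstance(angles, AngleSet) else np.asarray(angles, float)
    r = np.radians(a)
    return np.stack([np.sin(r), np.cos(r)], axis=-1).reshape(-1)


def decode_angles(enc) -> AngleSet:
    """atan2 decoding, folded to [0, 180] by absolute value.

    Scale-invariant per (sin, cos) pair; a numerically null pair is an error.
    """
    enc = np.asarray(enc, dtype=float).reshape(3, 2)
    out = []
    for s, c in enc:
        if math.hypot(s, c) < 1e-12:
            raise Rna3wjError("cannot decode a null (sin, cos) pair")
        out.append(abs(math.degrees(math.atan2(s, c))))
    return AngleSet(*out)


def loss(pred_encodings, truth_angles, mask=None) -> float:
    """Masked mean over valid samples of the summed squared (sin, cos) errors."""
    pred = np.asarray(pred_encodings, dtype=float).reshape(-1, 6)
    truth = np.vstack([encode_angles(a) for a in truth_angles])
    mask = np.ones(len(pred), dtype=bool) if mask is None else np.asarray(mask, bool)
    if mask.sum() == 0:
        raise Rna3wjError("loss undefined: no valid samples after masking")
    d = pred[mask] - truth[mask]
    return float(np.mean(np.sum(d * d, axis=1)))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (all overridable)."""

    hidden_dim: int = 64
    nucleotide_heads: int = 2
    head_heads: int = 2
    dropout: float = 0.2
    gate_mode: str = "per_dimension"  # or "scalar"
    variant: str = "full"
    lr: float = 1e-3
    weight_decay: float = 1e-2
    plateau_factor: float = 0.5
    plateau_patience: int = 25
    max_epochs: int = 500
    early_stop_patience: int = 60
    batch_size: int = 64
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.gate_mode not in ("per_dimension", "scalar"):
            raise ValueError("gate_mode must be 'per_dimension' or 'scalar'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# dataset and batching

@dataclass
class ChainSample:
    """One chain: featurization plus one (or no) angle triple per junction."""

    chain_id: str
    fc: FeaturizedChain
    angles: list  # AngleSet or None, aligned with fc.junction_node_ids


class JunctionDataset:
    """A list of chains, the unit of cross-validation splitting."""

    def __init__(self, samples):
        self.samples = list(samples)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, idx):
        return self.samples[idx]

    @property
    def n_junctions(self) -> int:
        return sum(len(s.fc.junction_node_ids) for s in self.samples)

    def subset(self, indices) -> "JunctionDataset":
        return JunctionDataset([self.samples[i] for i in indices])

    def truth(self) -> list:
        """All ground-truth angle triples, chain-major, junction order."""
        return [a for s in self.samples for a in s.angles]

    @classmethod
    def from_pairs(cls, triples) -> "JunctionDataset":
        """triples: iterable of (chain_id, SecondaryStructure, list-of-AngleSet)."""
        out = []
        for cid, ss, angles in triples:
            fc = featurize(ss)
            want = len(fc.junction_node_ids)
            if angles is None:
                angles = [None] * want
            if len(angles) != want:
                raise ContractError(
                    f"{cid}: {len(angles)} angle records for {want} junctions"
                )
            out.append(ChainSample(cid, fc, list(angles)))
        return cls(out)

    @classmethod
    def from_records(cls, records) -> "JunctionDataset":
        """From synthetic records (single planted junction per chain)."""
        from .secstruct import parse_dot_bracket

        return cls.from_pairs(
            (r.record_id, parse_dot_bracket(r.dot_bracket, r.sequence), [r.angles])
            for r in records
        )

    @classmethod
    def from_manifest(cls, manifest_path) -> "JunctionDataset":
        """From a dataset manifest CSV (id, dbn, theta1..theta3 columns)."""
        import pandas as pd

        from .secstruct import read_vienna

        root = Path(manifest_path).parent
        df = pd.read_csv(manifest_path)
        triples = []
        for _, row in df.iterrows():
            ss = read_vienna(root / row["dbn"])
            angles = [AngleSet(row["theta1"], row["theta2"], row["theta3"])]
            triples.append((str(row["id"]), ss, angles))
        return cls.from_pairs(triples)


@dataclass
class Batch:
    """Disjoint union of chain graphs with directed (doubled) edge lists."""

    nuc_x: np.ndarray
    nuc_src: np.ndarray
    nuc_dst: np.ndarray
    nuc_edge: np.ndarray
    n_tree: int
    tree_x: np.ndarray
    tree_src: np.ndarray
    tree_dst: np.ndarray
    tree_edge: np.ndarray
    pool_nt: np.ndarray
    pool_node: np.ndarray
    pool_counts: np.ndarray  # (n_tree, 1), >= 1
    junction_idx: np.ndarray
    targets: np.ndarray  # (J, 6)
    mask: np.ndarray  # (J,)


def _double(src, dst, attr):
    return (np.concatenate([src, dst]), np.concatenate([dst, src]),
            np.vstack([attr, attr]) if len(attr) else attr)


def collate(samples) -> Batch:
    nuc_x, nsrc, ndst, nedge = [], [], [], []
    tree_x, tsrc, tdst, tedge = [], [], [], []
    pool_nt, pool_node, junction_idx, targets, mask = [], [], [], [], []
    n_off = t_off = 0
    for s in samples:
        fc = s.fc
        g = fc.nuc_graph
        nuc_x.append(g.node_features)
        s2, d2, a2 = _double(g.edge_src, g.edge_dst, g.edge_types)
        nsrc.append(s2 + n_off)
        ndst.append(d2 + n_off)
        nedge.append(a2)
        tree_x.append(fc.tree_node_x)
        s2, d2, a2 = _double(fc.tree_edge_src, fc.tree_edge_dst, fc.tree_edge_x)
        tsrc.append(s2 + t_off)
        tdst.append(d2 + t_off)
        tedge.append(a2)
        pool_nt.append(fc.loop_member_nt + n_off)
        pool_node.append(fc.loop_member_node + t_off)
        for jid, ang in zip(fc.junction_node_ids, s.angles):
            junction_idx.append(jid + t_off)
            targets.append(encode_angles(ang) if ang is not None else np.zeros(6))
            mask.append(ang is not None)
        n_off += g.n_nodes
        t_off += fc.n_tree_nodes
    pool_node_arr = np.concatenate(pool_node) if pool_node else np.zeros(0, np.int64)
    counts = np.bincount(pool_node_arr, minlength=t_off).astype(float)
    return Batch(
        nuc_x=np.vstack(nuc_x),
        nuc_src=np.concatenate(nsrc),
        nuc_dst=np.concatenate(ndst),
        nuc_edge=np.vstack([e for e in nedge if len(e)]) if any(len(e) for e in nedge)
        else np.zeros((0, 3)),
        n_tree=t_off,
        tree_x=np.vstack(tree_x),
        tree_src=np.concatenate(tsrc) if tsrc else np.zeros(0, np.int64),
        tree_dst=np.concatenate(tdst) if tdst else np.zeros(0, np.int64),
        tree_edge=np.vstack([e for e in tedge if len(e)]) if any(len(e) for e in tedge)
        else np.zeros((0, F.TREE_EDGE_DIM)),
        pool_nt=np.concatenate(pool_nt) if pool_nt else np.zeros(0, np.int64),
        pool_node=pool_node_arr,
        pool_counts=np.maximum(counts, 1.0)[:, None],
        junction_idx=np.array(junction_idx, dtype=np.int64),
        targets=np.vstack(targets) if targets else np.zeros((0, 6)),
        mask=np.array(mask, dtype=bool),
    )


# ---------------------------------------------------------------------------
# network

class DualResolutionNet:
    """The parameterized network; built once per (config, seed)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        h = cfg.hidden_dim
        attn = cfg.variant != "gcn_message_passing"
        self.layers = {}
        node_in = F.LEN_ONLY_DIM if cfg.variant == "len_only_features" else F.TREE_NODE_DIM
        self.tree_node_in = node_in
        if cfg.variant != "no_nucleotide":
            self.layers["nuc"] = TransformerConv(
                rng, F.NUC_NODE_DIM, h, heads=cfg.nucleotide_heads,
                edge_dim=3, attention=attn)
        if cfg.variant != "no_tree":
            self.layers["node_enc"] = Linear(rng, node_in, h)
            self.layers["edge_enc"] = Linear(rng, F.TREE_EDGE_DIM, h)
        if cfg.variant in ("full", "gcn_message_passing", "len_only_features"):
            gate_out = h if cfg.gate_mode == "per_dimension" else 1
            self.layers["gate"] = Linear(rng, 2 * h, gate_out)
        elif cfg.variant == "concat_fusion":
            self.layers["fuse"] = Linear(rng, 2 * h, h)
        self.layers["ln"] = LayerNorm(h)
        self.layers["gat"] = GATConv(rng, h, heads=cfg.head_heads,
                                     edge_dim=h, attention=attn)
        self.layers["mlp1"] = Linear(rng, h, h)
        self.layers["mlp2"] = Linear(rng, h, 6)
        self.fingerprint = FEATURE_FINGERPRINT

    def parameters(self) -> list:
        return [t for lname in sorted(self.layers) for _, t in
                sorted(self.layers[lname].parameters().items())]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {f"{lname}.{pname}": t.data.copy()
                for lname in sorted(self.layers)
                for pname, t in sorted(self.layers[lname].parameters().items())}

    def load_state(self, state: dict) -> None:
        for lname in self.layers:
            for pname, t in self.layers[lname].parameters().items():
                key = f"{lname}.{pname}"
                if state[key].shape != t.data.shape:
                    raise ContractError(
                        f"parameter {key}: checkpoint shape {state[key].shape} "
                        f"!= model shape {t.data.shape}")
                t.data = state[key].copy()

    # -- forward ----------------------------------------------------------
    def forward(self, batch: Batch, rng=None, training: bool = False) -> Tensor:
        cfg = self.cfg
        p = cfg.dropout
        if batch.tree_x.shape[1] < self.tree_node_in:
            raise ContractError(
                f"tree node features have {batch.tree_x.shape[1]} dims, "
                f"model expects {self.tree_node_in}")
        h_nuc = None
        if cfg.variant != "no_nucleotide":
            emb = self.layers["nuc"](Tensor(batch.nuc_x), batch.nuc_src,
                                     batch.nuc_dst, Tensor(batch.nuc_edge))
            emb = dropout(emb.relu(), p, rng, training)
            pooled = segment_sum(gather_rows(emb, batch.pool_nt),
                                 batch.pool_node, batch.n_tree)
            h_nuc = pooled * Tensor(1.0 / batch.pool_counts)
        h_tree = edge_emb = None
        if cfg.variant != "no_tree":
            tx = batch.tree_x[:, :self.tree_node_in]
            h_tree = dropout(self.layers["node_enc"](Tensor(tx)).relu(),
                             p, rng, training)
            edge_emb = self.layers["edge_enc"](Tensor(batch.tree_edge)).relu() \
                if batch.tree_edge.shape[0] else Tensor(np.zeros((0, cfg.hidden_dim)))
        if cfg.variant == "no_tree":
            h = h_nuc
            edge_emb = Tensor(np.zeros((len(batch.tree_src), cfg.hidden_dim)))
        elif cfg.variant == "no_nucleotide":
            h = h_tree
        elif cfg.variant == "concat_fusion":
            h = self.layers["fuse"](concat([h_nuc, h_tree], axis=1))
        else:
            z = self.layers["gate"](concat([h_nuc, h_tree], axis=1)).sigmoid()
            h = z * h_nuc + (1.0 - z) * h_tree
        hn = self.layers["ln"](h)
        gat = self.layers["gat"](hn, batch.tree_src, batch.tree_dst, edge_emb)
        res = hn + dropout(gat, p, rng, training)
        out = gather_rows(res, batch.junction_idx)
        out = dropout(self.layers["mlp1"](out).relu(), p, rng, training)
        return self.layers["mlp2"](out)

    def loss_tensor(self, pred: Tensor, batch: Batch) -> Tensor:
        valid = np.where(batch.mask)[0]
        if len(valid) == 0:
            raise Rna3wjError("loss undefined: no valid samples after masking")
        d = pred - Tensor(batch.targets)
        row = (d * d).sum(axis=1).reshape(-1, 1)
        return gather_rows(row, valid).sum() * (1.0 / len(valid))


def build_variant(cfg: ModelConfig, seed=None) -> DualResolutionNet:
    """Initialized network skeleton for the configured ablation variant."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return DualResolutionNet(cfg, rng)


# ---------------------------------------------------------------------------
# Model / Results

class JunctionAngleModel:
    """Angle-regression model bound to a dataset.

    Parameters
    ----------
    dataset : JunctionDataset (chains with ground-truth angle triples).
    config : ModelConfig, defaults used when omitted.
    """

    def __init__(self, dataset: JunctionDataset, config: ModelConfig = None):
        self.dataset = dataset
        self.config = config if config is not None else ModelConfig()

    @classmethod
    def from_records(cls, records, config: ModelConfig = None):
        return cls(JunctionDataset.from_records(records), config)

    @classmethod
    def from_manifest(cls, manifest_path, config: ModelConfig = None):
        return cls(JunctionDataset.from_manifest(manifest_path), config)

    # -- training ---------------------------------------------------------
    def fit(self, seed=None, verbose: bool = False) -> "JunctionAngleResults":
        """Train with AdamW + plateau LR decay + early stopping.

        A single integer seed drives weight initialization, the
        train/validation split, batch shuffling and dropout, so identical
        seeds give identical results.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        master = np.random.default_rng(seed)
        init_rng, split_rng, shuffle_rng, drop_rng = master.spawn(4)
        net = DualResolutionNet(cfg, init_rng)
        n = len(self.dataset)
        if n < 2:
            raise Rna3wjError("training needs at least 2 chains")
        order = split_rng.permutation(n)
        n_val = int(round(cfg.val_fraction * n))
        n_val = min(max(n_val, 0), n - 1)
        val_idx, train_idx = order[:n_val], order[n_val:]
        train_set = self.dataset.subset(train_idx)
        val_batch = collate(self.dataset.subset(val_idx).samples) if n_val else None

        opt = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
        history = []
        best = (np.inf, net.state_dict(), 0)
        bad = 0
        for epoch in range(cfg.max_epochs):
            perm = shuffle_rng.permutation(len(train_set))
            total, count = 0.0, 0
            for start in range(0, len(perm), cfg.batch_size):
                chunk = perm[start:start + cfg.batch_size]
                batch = collate([train_set[i] for i in chunk])
                if batch.mask.sum() == 0:
                    continue
                opt.zero_grad()
                pred = net.forward(batch, rng=drop_rng, training=True)
                L = net.loss_tensor(pred, batch)
                if not np.isfinite(L.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}: {L.data}")
                L.backward()
                opt.step()
                total += float(L.data) * int(batch.mask.sum())
                count += int(batch.mask.sum())
            train_loss = total / max(count, 1)
            if val_batch is not None:
                vpred = net.forward(val_batch, training=False)
                val_loss = float(net.loss_tensor(vpred, val_batch).data)
            else:
                val_loss = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "lr": opt.lr})
            if verbose and epoch % 10 == 0:
                print(f"epoch {epoch:4d}  train {train_loss:.5f}  "
                      f"val {val_loss:.5f}  lr {opt.lr:.2e}")
            monitored = val_loss
            if monitored < best[0] - 1e-9:
                best = (monitored, net.state_dict(), epoch)
                bad = 0
            else:
                bad += 1
                if bad > cfg.early_stop_patience:
                    break
            sched.step(monitored)
        net.load_state(best[1])
        return JunctionAngleResults(
            network=net, config=cfg, history=history, seed=seed,
            best_epoch=best[2],
            train_chain_ids=[train_set[i].chain_id for i in range(len(train_set))],
            val_chain_ids=[self.dataset[i].chain_id for i in val_idx],
        )

    def cross_validate(self, k: int = 5, taus=(10.0, 15.0, 20.0), seed=None):
        """Chain-level k-fold cross-validation (junctions of a chain never
        straddle folds).  Returns per-fold metric dicts plus their mean."""
        from .evaluation import acc, angular_error

        cfg = self.config
        seed = cfg.seed if seed is None else seed
        n = len(self.dataset)
        if k > n:
            raise Rna3wjError(f"k={k} folds but only {n} chains")
        order = np.random.default_rng(seed).permutation(n)
        folds = [sorted(order[i::k].tolist()) for i in range(k)]
        reports = []
        for fi, test_idx in enumerate(folds):
            train_idx = [i for i in range(n) if i not in set(test_idx)]
            sub = JunctionAngleModel(self.dataset.subset(train_idx), cfg)
            res = sub.fit(seed=seed + fi + 1)
            test_set = self.dataset.subset(test_idx)
            preds = res.predict_dataset(test_set)
            errors = np.vstack([
                angular_error(p, t)
                for p, t in zip(preds, test_set.truth())
            ])
            rep = {"fold": fi, "n_chains": len(test_idx), "n_junctions": len(errors)}
            for tau in taus:
                a = acc(errors, tau)
                rep[f"acc_{tau:g}"] = a.overall
                rep[f"joint_acc_{tau:g}"] = a.joint
            reports.append(rep)
        mean = {key: float(np.mean([r[key] for r in reports]))
                for key in reports[0] if key not in ("fold",)}
        return {"folds": reports, "mean": mean,
                "fold_indices": folds, "seed": seed}


@dataclass
class JunctionAngleResults:
    """Trained model: weights, config, history and prediction methods."""

    network: DualResolutionNet
    config: ModelConfig
    history: list
    seed: int
    best_epoch: int
    train_chain_ids: list = field(default_factory=list)
    val_chain_ids: list = field(default_factory=list)

    # -- prediction -------------------------------------------------------
    def _predict_batch(self, batch: Batch) -> np.ndarray:
        return self.network.forward(batch, training=False).data

    def predict(self, ss) -> list:
        """Predict angle triples for every three-way junction of one chain.

        Accepts a :class:`SecondaryStructure` or a featurized chain;
        returns ``[(junction_node_id, AngleSet), ...]`` (empty when the
        chain has no three-way junction).
        """
        fc = featurize(ss) if isinstance(ss, SecondaryStructure) else ss
        if self.network.fingerprint != FEATURE_FINGERPRINT:
            raise ContractError("feature layout fingerprint mismatch")
        if not fc.junction_node_ids:
            return []
        sample = ChainSample("query", fc, [None] * len(fc.junction_node_ids))
        enc = self._predict_batch(collate([sample]))
        return [(jid, decode_angles(e)) for jid, e in zip(fc.junction_node_ids, enc)]

    def predict_dataset(self, dataset: JunctionDataset) -> list:
        """Flat list of AngleSet predictions, chain-major, junction order."""
        if not len(dataset):
            return []
        enc = self._predict_batch(collate(dataset.samples))
        return [decode_angles(e) for e in enc]

    def evaluate(self, dataset: JunctionDataset, taus=(10.0, 15.0, 20.0)) -> dict:
        from .evaluation import acc, angular_error

        preds = self.predict_dataset(dataset)
        truth = dataset.truth()
        errors = np.vstack([angular_error(p, t) for p, t in zip(preds, truth)])
        out = {"n_junctions": len(errors),
               "mae": float(np.mean(errors))}
        for tau in taus:
            a = acc(errors, tau)
            out[f"acc_{tau:g}"] = a.overall
            out[f"joint_acc_{tau:g}"] = a.joint
            out[f"per_angle_acc_{tau:g}"] = a.per_angle
        return out

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Junction angle model (dual-resolution attention GNN)",
            "=" * 56,
            f"variant:            {cfg.variant}",
            f"hidden dim:         {cfg.hidden_dim}",
            f"parameters:         {self.network.n_parameters()}",
            f"seed:               {self.seed}",
            f"epochs run:         {len(self.history)}",
            f"best epoch:         {self.best_epoch}",
        ]
        if self.history:
            lines += [
                f"final train loss:   {self.history[-1]['train_loss']:.6f}",
                f"final val loss:     {self.history[-1]['val_loss']:.6f}",
            ]
        lines += [
            f"train chains:       {len(self.train_chain_ids)}",
            f"val chains:         {len(self.val_chain_ids)}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights + config + feature fingerprint + history."""
        meta = {
            "config": self.config.to_dict(),
            "fingerprint": self.network.fingerprint,
            "history": self.history,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "train_chain_ids": self.train_chain_ids,
            "val_chain_ids": self.val_chain_ids,
        }
        arrays = {f"param:{k}": v for k, v in self.network.state_dict().items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "JunctionAngleResults":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        if meta["fingerprint"] != FEATURE_FINGERPRINT:
            raise ContractError(
                "checkpoint feature fingerprint does not match this package version")
        net = build_variant(cfg)
        net.load_state({k[len("param:"):]: data[k] for k in data.files
                        if k.startswith("param:")})
        return cls(network=net, config=cfg, history=meta["history"],
                   seed=meta["seed"], best_epoch=meta["best_epoch"],
                   train_chain_ids=meta["train_chain_ids"],
                   val_chain_ids=meta["val_chain_ids"])

    def write_history_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.history).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# functional wrappers matching the operation names

def train(dataset: JunctionDataset, cfg: ModelConfig = None,
          seed=None) -> JunctionAngleResults:
    return JunctionAngleModel(dataset, cfg).fit(seed=seed)


def cross_validate(dataset: JunctionDataset, k: int = 5, cfg: ModelConfig = None,
                   seed=None, taus=(10.0, 15.0, 20.0)):
    return JunctionAngleModel(dataset, cfg).cross_validate(k=k, taus=taus, seed=seed)


def predict(results: JunctionAngleResults, ss) -> list:
    return results.predict(ss)
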