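"""Angle encoding, network layers, loss, training and ablation contracts."""

import math

import numpy as np
import pytest

from rna3wj.errors import ContractError, Rna3wjError
from rna3wj.geometry import AngleSet
from rna3wj.model import (ChainSample, DualResolutionNet, JunctionAngleModel,
                          JunctionAngleResults, JunctionDataset, ModelConfig,
                          build_variant, collate, decode_angles, encode_angles,
                          loss)
from rna3wj.features import featurize
from rna3wj.secstruct import parse_dot_bracket


class TestAngleEncoding:
    @pytest.mark.parametrize("angles,expected", [
        ((90, 90, 90), [1, 0, 1, 0, 1, 0]),
        ((0, 90, 180), [0, 1, 1, 0, 0, -1]),
        ((60, 60, 60), [math.sqrt(3) / 2, 0.5] * 3),
    ])
    def test_encode_examples(self, angles, expected):
        assert np.allclose(encode_angles(AngleSet(*angles)), expected, atol=1e-9)

    def test_decode_examples(self):
        assert np.allclose(decode_angles([1, 0, 1, 0, 1, 0]).as_array(), 90)
        # scale invariance per pair
        assert decode_angles([0.2, 0, 1, 0, 1, 0]).theta1 == pytest.approx(90)
        # negative sine folded by absolute value
        a = decode_angles([-0.5, -math.sqrt(3) / 2, 1, 0, 1, 0])
        assert a.theta1 == pytest.approx(150, abs=1e-9)

    def test_decode_encode_identity(self):
        rng = np.random.default_rng(0)
        for t in rng.uniform(0.001, 179.999, size=(200, 3)):
            back = decode_angles(encode_angles(AngleSet(*t))).as_array()
            assert np.allclose(back, t, atol=1e-9)

    def test_null_pair_rejected(self):
        with pytest.raises(Rna3wjError):
            decode_angles([0, 0, 1, 0, 1, 0])


class TestLoss:
    def test_zero_iff_exact(self):
        truth = [AngleSet(30, 100, 170)]
        assert loss([encode_angles(truth[0])], truth) == 0.0
        perturbed = encode_angles(truth[0]) + np.array([0.1, 0, 0, 0, 0, 0])
        assert loss([perturbed], truth) > 0

    def test_orthogonal_unit_circle_value(self):
        # truth (90,90,90) -> pairs (1,0); predicting (0,1) per angle:
        # squared chord 2 per angle, 6 in total
        pred = np.array([0, 1, 0, 1, 0, 1.0])
        assert loss([pred], [AngleSet(90, 90, 90)]) == pytest.approx(6.0)

    def test_masking_contract(self):
        truth = [AngleSet(90, 90, 90), AngleSet(10, 10, 10)]
        preds = [np.array([0, 1, 0, 1, 0, 1.0]), np.zeros(6)]
        single = loss([preds[0]], [truth[0]])
        assert loss(preds, truth, mask=[True, False]) == pytest.approx(single)
        with pytest.raises(Rna3wjError):
            loss(preds, truth, mask=[False, False])

    def test_sample_order_invariant(self):
        rng = np.random.default_rng(3)
        truth = [AngleSet(*a) for a in rng.uniform(10, 170, size=(5, 3))]
        preds = list(rng.normal(size=(5, 6)))
        assert loss(preds, truth) == pytest.approx(
            loss(preds[::-1], truth[::-1]))


def _fc(db, seq):
    return featurize(parse_dot_bracket(db, seq))


def _single_batch(fc, angles=None):
    n = len(fc.junction_node_ids)
    angles = [angles] * n if isinstance(angles, AngleSet) else [None] * n
    return collate([ChainSample("c", fc, angles)])


class TestNucleotideEncoder:
    def test_isolated_node_is_self_transform(self):
        from rna3wj.autodiff import Tensor
        from rna3wj.layers import TransformerConv

        rng = np.random.default_rng(0)
        conv = TransformerConv(rng, 11, 8, heads=2, edge_dim=3)
        x = np.zeros((1, 11))
        x[0, 0] = 1.0
        out = conv(Tensor(x), np.zeros(0, np.int64), np.zeros(0, np.int64),
                   Tensor(np.zeros((0, 3))))
        expected = x @ conv.Wskip.data + conv.b.data
        assert np.allclose(out.data, expected)

    def test_matches_dense_attention_oracle(self):
        """Hand-rolled dense attention on a 3-node path reproduces the layer."""
        from rna3wj.autodiff import Tensor
        from rna3wj.layers import TransformerConv

        rng = np.random.default_rng(1)
        conv = TransformerConv(rng, 4, 6, heads=2, edge_dim=3)
        x = rng.normal(size=(3, 4))
        src = np.array([0, 1, 1, 2])  # path edges doubled
        dst = np.array([1, 0, 2, 1])
        ea = np.tile(np.array([[1.0, 0, 0]]), (4, 1))
        out = conv(Tensor(x), src, dst, Tensor(ea)).data

        H, D = 2, 3
        q = (x @ conv.Wq.data).reshape(3, H, D)
        k = (x @ conv.Wk.data + (ea[:1] @ conv.Wek.data)).reshape(3, H, D)
        v = (x @ conv.Wv.data + (ea[:1] @ conv.Wev.data)).reshape(3, H, D)
        expected = x @ conv.Wskip.data + conv.b.data
        for i in range(3):
            nbrs = [s for s, d in zip(src, dst) if d == i]
            scores = np.array([(q[i] * k[j]).sum(axis=1) / math.sqrt(D)
                               for j in nbrs])  # (|N|, H)
            alpha = np.exp(scores - scores.max(axis=0))
            alpha /= alpha.sum(axis=0)
            agg = sum(alpha[a][:, None] * v[j] for a, j in enumerate(nbrs))
            expected[i] += agg.reshape(-1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_permutation_equivariance_of_forward(self):
        """Re-indexing junction-equivalent chains leaves predictions fixed."""
        db = ".((.((...)).((...)).))."
        seq = "AGGAGGAAACCACCUUUGGAGGA"[:len(db)]
        fc = _fc(db, "A" * len(db))
        cfg = ModelConfig(hidden_dim=16, dropout=0.0)
        net = build_variant(cfg, seed=7)
        b = _single_batch(fc)
        out1 = net.forward(b).data
        out2 = net.forward(b).data
        assert np.array_equal(out1, out2)  # deterministic repeatability


class TestPooling:
    def test_mean_pool_known_vectors(self):
        from rna3wj.autodiff import Tensor, gather_rows, segment_sum

        emb = Tensor(np.array([[2.0, 0], [0, 4.0], [4.0, 2.0]]))
        members = np.array([0, 1, 2])
        nodes = np.array([0, 0, 1])
        pooled = segment_sum(gather_rows(emb, members), nodes, 2).data
        counts = np.array([[2.0], [1.0]])
        assert np.allclose(pooled / counts, [[1, 2], [4, 2]])


class TestGatedFusion:
    def test_forced_gate_limits(self):
        from rna3wj.autodiff import Tensor

        h_n = Tensor(np.array([[2.0, 0.0]]))
        h_t = Tensor(np.array([[0.0, 2.0]]))
        for z, expected in ((1.0, [2, 0]), (0.0, [0, 2]), (0.5, [1, 1])):
            zt = Tensor(np.full((1, 2), z))
            h = zt * h_n + (1.0 - zt) * h_t
            assert np.allclose(h.data, [expected])


class TestVariants:
    def test_exactly_one_variant_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="both_somehow")

    def test_no_nucleotide_ignores_nucleotide_graph(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=16, dropout=0.0, variant="no_nucleotide")
        net = build_variant(cfg, seed=3)
        batch = collate(tiny_dataset.samples[:2])
        out1 = net.forward(batch).data
        batch.nuc_x = np.zeros_like(batch.nuc_x)  # perturb nucleotide features
        out2 = net.forward(batch).data
        assert np.array_equal(out1, out2)

    def test_no_tree_ignores_tree_features(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=16, dropout=0.0, variant="no_tree")
        net = build_variant(cfg, seed=3)
        batch = collate(tiny_dataset.samples[:2])
        out1 = net.forward(batch).data
        batch.tree_x = np.zeros_like(batch.tree_x)
        batch.tree_edge = np.zeros_like(batch.tree_edge)
        out2 = net.forward(batch).data
        assert np.array_equal(out1, out2)

    def test_parameter_counts_differ(self):
        counts = {v: build_variant(ModelConfig(variant=v), seed=0).n_parameters()
                  for v in ("full", "no_tree", "no_nucleotide", "len_only_features",
                            "concat_fusion")}
        assert counts["no_tree"] < counts["full"]
        assert counts["no_nucleotide"] < counts["full"]
        assert counts["len_only_features"] < counts["full"]
        # per-dimension gate (2h -> h affine) has exactly the shape of the
        # concat-fusion projection, so those two counts coincide ...
        assert counts["concat_fusion"] == counts["full"]
        # ... while a scalar gate (2h -> 1) is smaller by (2h*h+h)-(2h+1)
        h = ModelConfig().hidden_dim
        scalar = build_variant(ModelConfig(gate_mode="scalar"), seed=0)
        assert counts["full"] - scalar.n_parameters() \
            == (2 * h * h + h) - (2 * h + 1)

    def test_len_only_rejects_full_checkpoint_shapes(self):
        full = build_variant(ModelConfig(variant="full"), seed=0)
        lenonly = build_variant(ModelConfig(variant="len_only_features"), seed=0)
        with pytest.raises(ContractError):
            lenonly.load_state(full.state_dict())


class TestTraining:
    def test_two_sample_overfit(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=32, max_epochs=500, batch_size=2,
                          val_fraction=0.0, dropout=0.0, weight_decay=0.0)
        ds = tiny_dataset.subset([0, 1])
        res = JunctionAngleModel(ds, cfg).fit(seed=0)
        assert min(h["train_loss"] for h in res.history) < 0.01

    def test_seed_determinism(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=16, max_epochs=3, val_fraction=0.0)
        r1 = JunctionAngleModel(tiny_dataset, cfg).fit(seed=5)
        r2 = JunctionAngleModel(tiny_dataset, cfg).fit(seed=5)
        s1, s2 = r1.network.state_dict(), r2.network.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        assert r1.history == r2.history

    def test_zero_epoch_returns_initialized_model(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=16, max_epochs=0)
        res = JunctionAngleModel(tiny_dataset, cfg).fit(seed=0)
        assert res.history == []
        init = build_variant(cfg, seed=None)  # not compared; just constructible
        assert res.network.n_parameters() == init.n_parameters()

    def test_checkpoint_round_trip_bit_identical(self, tiny_dataset, fast_config,
                                                 tmp_path):
        res = JunctionAngleModel(tiny_dataset, fast_config).fit(seed=1)
        p = tmp_path / "ckpt.npz"
        res.save(p)
        res2 = JunctionAngleResults.load(p)
        s1, s2 = res.network.state_dict(), res2.network.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        ss = tiny_dataset.samples[0].fc
        p1 = res.predict(ss)
        p2 = res2.predict(ss)
        assert all(np.array_equal(a[1].as_array(), b[1].as_array())
                   for a, b in zip(p1, p2))

    def test_summary_mentions_key_facts(self, tiny_dataset, fast_config):
        res = JunctionAngleModel(tiny_dataset, fast_config).fit(seed=1)
        s = res.summary()
        assert "variant" in s and "parameters" in s and "epochs" in s


class TestPredict:
    def test_chain_without_junction_gives_empty_list(self, tiny_dataset,
                                                     fast_config):
        res = JunctionAngleModel(tiny_dataset, fast_config).fit(seed=0)
        ss = parse_dot_bracket("((....))", "GGAAAACC")
        assert res.predict(ss) == []

    def test_deterministic_across_calls(self, tiny_dataset, fast_config):
        res = JunctionAngleModel(tiny_dataset, fast_config).fit(seed=0)
        ss = tiny_dataset.samples[0].fc
        a = res.predict(ss)
        b = res.predict(ss)
        assert np.array_equal(a[0][1].as_array(), b[0][1].as_array())

    def test_overfit_recovers_planted_angles(self, tiny_dataset):
        cfg = ModelConfig(hidden_dim=32, max_epochs=500, batch_size=2,
                          val_fraction=0.0, dropout=0.0, weight_decay=0.0)
        ds = tiny_dataset.subset([0, 1])
        res = JunctionAngleModel(ds, cfg).fit(seed=0)
        preds = res.predict_dataset(ds)
        for pred, truth in zip(preds, ds.truth()):
            assert np.allclose(pred.as_array(), truth.as_array(), atol=5.0)


class TestCrossValidate:
    def test_fold_partition_and_reproducibility(self, tiny_dataset, fast_config):
        model = JunctionAngleModel(tiny_dataset, fast_config)
        rep = model.cross_validate(k=2, seed=3)
        folds = rep["fold_indices"]
        assert len(folds) == 2
        union = sorted(i for f in folds for i in f)
        assert union == list(range(len(tiny_dataset)))
        rep2 = model.cross_validate(k=2, seed=3)
        assert rep2["fold_indices"] == folds
        assert rep["mean"] == rep2["mean"]

    def test_too_many_folds_rejected(self, tiny_dataset, fast_config):
        with pytest.raises(Rna3wjError):
            JunctionAngleModel(tiny_dataset, fast_config).cross_validate(k=99)
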