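"""Configuration invariants, assembly, losses, metrics, checkpoints."""

import numpy as np
import pytest

from atomgps.graph_core import DatasetSplit, make_split
from atomgps.layers import GPSLayer, MultiHeadAttention
from atomgps.model import (AtomGraphModel, ChannelLayout, ModelConfig,
                           PreparedDataset, TaskSpec, load_checkpoint,
                           metrics, multitask_loss, parameter_count,
                           save_checkpoint, task_losses)
from atomgps.synthetic import GenSpec, generate_dataset
from atomgps.encoders import filter_invalid


def small_dataset(target="local", scheme_needs_enc=True, seed=7):
    spec = GenSpec(n_graphs=20, n_atoms=(8, 12), r_c=3.0, target=target,
                   seed=seed)
    graphs = generate_dataset(spec)
    kept, _, _ = filter_invalid(graphs, 2)
    return DatasetSplit(graphs=kept, split=make_split(len(kept), seed))


class TestModelConfig:
    def test_scheme_flag_consistency(self):
        assert ModelConfig(global_attn_engine=False, use_encodings=False).scheme == "S1"
        assert ModelConfig.for_scheme("S4", hidden_dim=16).scheme == "S4"

    def test_attention_needs_heads(self):
        with pytest.raises(ValueError):
            ModelConfig(global_attn_engine=True, global_attn_heads=0)

    def test_heads_zero_when_attention_off(self):
        with pytest.raises(ValueError):
            ModelConfig(global_attn_engine=False, global_attn_heads=2)

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(global_attn_engine=True, global_attn_heads=4,
                        hidden_dim=18)

    def test_geometric_backbone_needs_coords(self):
        with pytest.raises(ValueError):
            ModelConfig(mpnn_type="geometric-mpnn", has_pos=False)


class TestAssembly:
    def test_s1_has_no_attention_parameters(self):
        cfg = ModelConfig.for_scheme("S1", hidden_dim=8,
                                     tasks=[TaskSpec("local")])
        model = AtomGraphModel(cfg, ChannelLayout(p=1, f=1), seed=0)
        assert not any(isinstance(c, GPSLayer) for c in model.convs)

    def test_s4_layer_and_head_structure(self):
        cfg = ModelConfig.for_scheme("S4", hidden_dim=16, num_conv_layers=3,
                                     global_attn_heads=2, lpe_dim=2,
                                     tasks=[TaskSpec("local")])
        model = AtomGraphModel(cfg, ChannelLayout(p=1, f=1, d_l=2), seed=0)
        assert len(model.convs) == 3
        for conv in model.convs:
            assert isinstance(conv, GPSLayer)
            assert isinstance(conv.attn, MultiHeadAttention)
            assert conv.attn.heads == 2

    def test_parameter_count_monotone_in_hidden_dim(self):
        layout = ChannelLayout(p=1, f=1, d_l=2)
        counts = [parameter_count(AtomGraphModel(
            ModelConfig.for_scheme("S2", hidden_dim=h, lpe_dim=2,
                                   tasks=[TaskSpec("local")]),
            layout, seed=0)) for h in (8, 16, 24, 32)]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_parameter_count_equals_sum_of_shapes(self):
        cfg = ModelConfig.for_scheme("S4", hidden_dim=8, lpe_dim=2,
                                     edge_embed_dim=4,
                                     tasks=[TaskSpec("local")])
        model = AtomGraphModel(cfg, ChannelLayout(p=1, f=1, d_l=2), seed=0)
        expect = sum(int(np.prod(p.shape)) for p in model.parameters())
        assert parameter_count(model) == expect

    def test_forward_shapes_graph_and_node_tasks(self):
        split = small_dataset("node_charge")
        cfg = ModelConfig.for_scheme("S2", hidden_dim=8, lpe_dim=2,
                                     tasks=[TaskSpec("node_charge",
                                                     level="node")])
        ds = PreparedDataset(split, cfg)
        model = AtomGraphModel(cfg, ds.layout(), seed=0)
        batch = ds.batch("val")
        out = model(batch)["node_charge"]
        assert out.shape == (batch.num_nodes, 1)


class TestLosses:
    def test_single_task_weight_one_is_identity(self):
        from atomgps.autodiff import Tensor

        loss = Tensor(np.array(0.7))
        assert multitask_loss({"a": loss}).item() == pytest.approx(0.7)

    def test_two_equal_losses_sum(self):
        from atomgps.autodiff import Tensor

        loss = Tensor(np.array(0.5))
        total = multitask_loss({"a": loss, "b": Tensor(np.array(0.5))},
                               {"a": 1.0, "b": 1.0})
        assert total.item() == pytest.approx(1.0)

    def test_zero_weight_task_gets_zero_gradient(self):
        split = small_dataset("local")
        cfg = ModelConfig.for_scheme(
            "S1", hidden_dim=6,
            tasks=[TaskSpec("local", weight=1.0)])
        ds = PreparedDataset(split, cfg)
        model = AtomGraphModel(cfg, ds.layout(), seed=0)
        batch = ds.batch("train")
        preds = model(batch)
        losses = task_losses(preds, batch, cfg.tasks)
        total = multitask_loss(losses, {"local": 0.0})
        total.backward()
        head_params = model.heads["local"].parameters()
        assert all(p.grad is None or np.all(p.grad == 0.0)
                   for p in head_params)


class TestMetrics:
    def test_perfect_predictions(self):
        m = metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                    "regression")
        assert m["mse"] == 0 and m["mae"] == 0
        assert m["pearson_r"] == pytest.approx(1.0)
        acc = metrics(np.eye(3), np.array([0, 1, 2]), "multiclass")
        assert acc["accuracy"] == pytest.approx(100.0)
        ap = metrics(np.array([[0.9], [0.1]]), np.array([[1.0], [0.0]]),
                     "multilabel")
        assert ap["map"] == pytest.approx(1.0)

    def test_hand_arithmetic_mae_mse(self):
        m = metrics(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]),
                    "regression")
        assert m["mae"] == pytest.approx(2.0 / 3.0)
        assert m["mse"] == pytest.approx(2.0 / 3.0)

    def test_single_positive_ranked_first_ap_one(self):
        scores = np.array([[0.9], [0.5], [0.2], [0.1]])
        truth = np.array([[1.0], [0.0], [0.0], [0.0]])
        assert metrics(scores, truth, "multilabel")["map"] == pytest.approx(1.0)

    def test_zero_variance_pearson_not_available(self):
        m = metrics(np.array([1.0, 1.0]), np.array([0.0, 1.0]), "regression")
        assert np.isnan(m["pearson_r"])

    def test_missing_labels_masked_per_label(self):
        truth = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, np.nan]])
        scores = np.array([[0.9, 0.1], [0.2, 0.9], [0.8, 0.5]])
        assert metrics(scores, truth, "multilabel")["map"] == pytest.approx(1.0)


class TestCheckpoint:
    def test_roundtrip_reproduces_outputs(self, tmp_path):
        split = small_dataset("local")
        cfg = ModelConfig.for_scheme("S4", hidden_dim=8, lpe_dim=2,
                                     edge_embed_dim=4,
                                     tasks=[TaskSpec("local")])
        ds = PreparedDataset(split, cfg)
        model = AtomGraphModel(cfg, ds.layout(), seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        batch = ds.batch("val")
        assert np.array_equal(model(batch)["local"].data,
                              back(batch)["local"].data)
        assert back.config == cfg
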