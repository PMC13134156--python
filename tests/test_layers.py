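"""Layer semantics: message passing, geometry, attention, hybrid fusion,
pooling."""

import numpy as np
import pytest

from atomgps.autodiff import Tensor
from atomgps.graph_core import GraphInvalidError
from atomgps.layers import (GPSLayer, GeometricEdgeEmbedding,
                            GeometricMPNNLayer, MLP, MPNNLayer,
                            MultiHeadAttention, geometric_features, pool)

from conftest import make_graph, rigid_motion


def path_edges(n):
    pairs = np.array([(i, i + 1) for i in range(n - 1)])
    both = np.concatenate([pairs, pairs[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    return both[order].T.copy()


class TestMPNNLayer:
    def test_no_edges_update_of_zero_aggregate(self, rng):
        layer = MPNNLayer(4, 4, rng, update_fn=lambda agg, h: agg + h)
        H = Tensor(rng.normal(size=(3, 4)))
        out = layer(H, np.empty((2, 0), dtype=int))
        assert np.array_equal(out.data, H.data)  # zero aggregate + identity

    def test_two_node_path_swaps_rows(self, rng):
        # phi = identity message, update returns the aggregate alone
        layer = MPNNLayer(4, 4, rng,
                          message_fn=lambda hu, hv, e: hv,
                          update_fn=lambda agg, h: agg)
        H = Tensor(rng.normal(size=(2, 4)))
        out = layer(H, path_edges(2))
        assert np.allclose(out.data, H.data[::-1])

    def test_neighbor_attention_weights_sum_to_one(self, rng):
        layer = MPNNLayer(4, 4, rng, aggregator="attention")
        H = Tensor(rng.normal(size=(5, 4)))
        ei = path_edges(5)
        alpha = layer.neighbor_attention_weights(H, ei)
        sums = np.zeros(5)
        np.add.at(sums, ei[0], alpha)
        assert np.allclose(sums, 1.0)

    def test_width_mismatch_errors(self, rng):
        layer = MPNNLayer(4, 4, rng, d_edge=3)
        with pytest.raises(ValueError):
            layer(Tensor(rng.normal(size=(2, 4))), path_edges(2),
                  Tensor(rng.normal(size=(2, 5))))

    def test_permutation_equivariance(self, rng):
        layer = MPNNLayer(4, 6, rng, aggregator="mean")
        H = rng.normal(size=(6, 4))
        ei = path_edges(6)
        perm = rng.permutation(6)
        out = layer(Tensor(H), ei).data
        ei_p = perm[ei]
        order = np.lexsort((ei_p[1], ei_p[0]))
        out_p = layer(Tensor(H[np.argsort(perm)]), ei_p[:, order]).data
        assert np.allclose(out_p[perm], out, atol=1e-10)


class TestGeometry:
    def test_right_angle(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        g = make_graph(3, [(0, 1), (0, 2)], coords=coords)
        state = geometric_features(coords, g.edge_index)
        # edge (0,1): other neighbor of 0 is 2 -> right angle
        col = [i for i, (u, v) in enumerate(state.edge_index.T)
               if (u, v) == (0, 1)][0]
        assert state.angles[col][0] == pytest.approx(np.pi / 2)

    def test_collinear_angles(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        g = make_graph(3, [(0, 1), (1, 2)], coords=coords)
        state = geometric_features(coords, g.edge_index)
        col = [i for i, (u, v) in enumerate(state.edge_index.T)
               if (u, v) == (1, 0)][0]
        assert state.angles[col][0] == pytest.approx(np.pi)

    def test_distances_rigid_invariant(self, rng):
        coords = rng.uniform(-2, 2, size=(6, 3))
        g = make_graph(6, [(i, i + 1) for i in range(5)], coords=coords)
        ref = geometric_features(coords, g.edge_index).distances
        moved = geometric_features(rigid_motion(coords, rng),
                                   g.edge_index).distances
        assert np.allclose(moved, ref, atol=1e-9)

    def test_coincident_atoms_invalid(self):
        coords = np.zeros((2, 3))
        g_ei = np.array([[0, 1], [1, 0]])
        with pytest.raises(GraphInvalidError):
            geometric_features(coords, g_ei)


class TestGeometricEdgeEmbedding:
    def test_degree_one_endpoint_is_radial_only(self, rng):
        emb = GeometricEdgeEmbedding(4, rng, r_c=3.0)
        coords = np.array([[0, 0, 0], [1.2, 0, 0]])
        ei = np.array([[0, 1], [1, 0]])
        state = geometric_features(coords, ei)
        rbf, ang = emb.basis(state)
        assert np.all(ang == 0.0)
        out = emb(state).data
        radial_only = (Tensor(rbf) @ emb.W_r.W).data
        assert np.array_equal(out, radial_only)

    def test_zeroed_angular_weights_depend_on_r_only(self, rng):
        emb = GeometricEdgeEmbedding(4, rng, r_c=3.0)
        emb.W_a.W.data[:] = 0.0
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ei = make_graph(3, [(0, 1), (0, 2), (1, 2)], coords=coords).edge_index
        out1 = emb(geometric_features(coords, ei)).data
        # moving atom 2 changes angles but not the (0,1) distance
        coords2 = coords.copy()
        coords2[2] = [0.3, 1.1, 0.2]
        ei2 = ei
        out2 = emb(geometric_features(coords2, ei2)).data
        col = [i for i, (u, v) in enumerate(ei.T) if (u, v) == (0, 1)][0]
        assert np.allclose(out1[col], out2[col])

    def test_doubling_identical_neighbors_doubles_angular_term(self, rng):
        emb = GeometricEdgeEmbedding(4, rng, r_c=3.0)
        state1 = geometric_features(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            make_graph(3, [(0, 1), (0, 2)]).edge_index)
        _, ang1 = emb.basis(state1)
        # two neighbors at the identical angle
        state2 = geometric_features(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0.0001]]),
            make_graph(4, [(0, 1), (0, 2), (0, 3)]).edge_index)
        _, ang2 = emb.basis(state2)
        col1 = [i for i, (u, v) in enumerate(state1.edge_index.T)
                if (u, v) == (0, 1)][0]
        col2 = [i for i, (u, v) in enumerate(state2.edge_index.T)
                if (u, v) == (0, 1)][0]
        assert np.allclose(ang2[col2], 2 * ang1[col1], rtol=1e-3)


class TestGeometricMPNN:
    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(-2, 2, size=(7, 3))
        g = make_graph(7, [(i, i + 1) for i in range(6)] + [(0, 3)],
                       coords=coords)
        emb = GeometricEdgeEmbedding(5, rng, r_c=6.0)
        layer = GeometricMPNNLayer(4, 4, 5, rng)
        H = Tensor(rng.normal(size=(7, 4)))

        def forward(c):
            state = geometric_features(c, g.edge_index)
            return layer(H, g.edge_index, emb(state)).data

        ref = forward(coords)
        for _ in range(5):
            assert np.allclose(forward(rigid_motion(coords, rng)), ref,
                               atol=1e-5)

    def test_single_edge_hand_computed(self, rng):
        # tiny widths, hand-evaluated xi/update composition
        emb = GeometricEdgeEmbedding(1, rng, r_c=3.0)
        layer = GeometricMPNNLayer(1, 1, 1, rng)
        coords = np.array([[0, 0, 0], [1.0, 0, 0]])
        g = make_graph(2, [(0, 1)], coords=coords)
        H = Tensor(np.array([[0.5], [-0.2]]))
        state = geometric_features(coords, g.edge_index)
        e_bar = emb(state)
        out = layer(H, g.edge_index, e_bar).data

        def mlp_eval(mlp, x):
            h = x @ mlp.layers[0].W.data + mlp.layers[0].b.data
            h = np.maximum(h, 0.0)
            return h @ mlp.layers[1].W.data + mlp.layers[1].b.data

        msg_to_0 = mlp_eval(layer.xi, np.concatenate(
            [H.data[0], H.data[1], e_bar.data[0]]).reshape(1, -1))
        expect_0 = mlp_eval(layer.upd, np.concatenate(
            [msg_to_0[0], H.data[0]]).reshape(1, -1))
        assert np.allclose(out[0], expect_0[0], atol=1e-12)


class TestMultiHeadAttention:
    def test_singleton_graph_attends_to_self(self, rng):
        attn = MultiHeadAttention(8, 2, rng)
        H = Tensor(rng.normal(size=(1, 8)))
        out = attn(H, np.array([0]))
        dense = attn.last_attention_dense()
        assert np.allclose(dense, 1.0)
        expect = (H.data @ attn.W_V.W.data) @ attn.W_O.W.data
        assert np.allclose(out.data, expect, atol=1e-12)

    def test_identical_rows_give_uniform_attention(self, rng):
        attn = MultiHeadAttention(8, 4, rng)
        H = Tensor(np.tile(rng.normal(size=(1, 8)), (5, 1)))
        attn(H, np.zeros(5, dtype=int))
        assert np.allclose(attn.last_attention_dense(), 1.0 / 5.0)

    def test_zero_mass_across_graph_boundary(self, rng):
        attn = MultiHeadAttention(8, 2, rng)
        H = Tensor(rng.normal(size=(7, 8)))
        member = np.array([0, 0, 0, 1, 1, 2, 2])
        attn(H, member)
        dense = attn.last_attention_dense()
        cross = member[:, None] != member[None, :]
        assert np.all(dense[:, cross] == 0.0)
        assert np.allclose(dense.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(dense >= 0.0)

    def test_head_divisibility_enforced(self, rng):
        with pytest.raises(ValueError):
            MultiHeadAttention(10, 4, rng)


class TestGPSLayer:
    def _build(self, rng, d=6):
        mpnn = MPNNLayer(d, d, np.random.default_rng(1))
        attn = MultiHeadAttention(d, 2, np.random.default_rng(2))
        fuse = MLP([d, d, d], np.random.default_rng(3))
        return mpnn, attn, fuse, GPSLayer(mpnn, attn, fuse)

    def test_zero_attention_is_pure_local_bitwise(self, rng):
        mpnn, attn, fuse, gps = self._build(rng)
        attn.W_O.W.data[:] = 0.0
        H = Tensor(rng.normal(size=(8, 6)))
        ei = path_edges(8)
        out, _ = gps(H, ei, np.zeros(8, dtype=int))
        ref = fuse(mpnn(H, ei))
        assert np.array_equal(out.data, ref.data)

    def test_zero_mpnn_is_pure_global(self, rng):
        mpnn, attn, fuse, gps = self._build(rng)
        zero = lambda H, ei, E=None: Tensor(np.zeros((H.shape[0], 6)))
        gps.mpnn = type("Z", (), {"__call__": lambda s, *a, **k: zero(*a, **k),
                                  "parameters": lambda s: []})()
        H = Tensor(rng.normal(size=(8, 6)))
        out, _ = gps(H, path_edges(8), np.zeros(8, dtype=int))
        ref = fuse(attn(H, np.zeros(8, dtype=int)))
        assert np.array_equal(out.data, ref.data)

    def test_equal_branches_sum_rule(self, rng):
        _, _, fuse, _ = self._build(rng)
        Y = Tensor(rng.normal(size=(4, 6)))
        assert np.allclose(fuse(Y + Y).data, fuse(2.0 * Y).data)


class TestPooling:
    def test_single_node_any_mode(self, rng):
        H = Tensor(rng.normal(size=(1, 5)))
        for mode in ("min", "max", "sum", "mean"):
            assert np.allclose(pool(H, np.array([0]), 1, mode).data, H.data)

    def test_sum_of_identical_rows(self):
        row = np.array([[1.0, 2.0]])
        H = Tensor(np.tile(row, (2, 1)))
        assert np.allclose(pool(H, np.zeros(2, dtype=int), 1, "sum").data,
                           2 * row)

    def test_mean_permutation_invariant(self, rng):
        H = rng.normal(size=(6, 3))
        member = np.array([0, 0, 0, 1, 1, 1])
        ref = pool(Tensor(H), member, 2, "mean").data
        perm = np.array([2, 0, 1, 5, 3, 4])
        assert np.allclose(pool(Tensor(H[perm]), member, 2, "mean").data, ref)

    def test_empty_graph_errors(self, rng):
        with pytest.raises(ValueError):
            pool(Tensor(rng.normal(size=(2, 3))), np.array([0, 0]), 2)
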