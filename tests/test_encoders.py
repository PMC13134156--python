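"""Chemical descriptors, topological encodings, Laplacian PE, and the
standardize/discard pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from atomgps.encoders import (apply_standardizer, chemical_descriptors,
                              compute_bundle, edge_topological_encodings,
                              element_table, filter_invalid, fit_standardizer,
                              laplacian_pe, node_topological_encodings,
                              NODE_TOPOLOGY_NAMES)
from atomgps.graph_core import GraphInvalidError

from conftest import make_graph, random_connected_graph


class TestChemicalDescriptors:
    def test_fifteen_columns(self):
        assert chemical_descriptors([1, 6, 8, 26]).shape == (4, 15)

    def test_identical_atoms_identical_rows(self):
        c = chemical_descriptors([6, 6])
        assert np.array_equal(c[0], c[1])

    def test_carbon_spot_values(self):
        table = element_table()
        assert table.value(6, "en_pauling") == pytest.approx(2.55)
        assert table.value(6, "atomic_weight") == pytest.approx(12.011)
        assert table.value(6, "group") == 14
        assert table.value(6, "block") == 1  # p-block ordinal

    def test_complete_for_z_1_to_86(self):
        c = chemical_descriptors(np.arange(1, 87))
        assert c.shape == (86, 15)
        # structural columns are always known even when physics is missing
        assert np.all(np.isfinite(c[:, :5]))

    def test_noble_gas_missing_values_are_nan(self):
        helium = chemical_descriptors([2])[0]
        assert np.isnan(helium[7])  # no Pauling electronegativity
        assert np.isnan(helium[9])  # no bound anion

    def test_out_of_range_z_named(self):
        with pytest.raises(GraphInvalidError, match="87"):
            chemical_descriptors([87])


class TestNodeTopology:
    def test_triangle_closed_forms(self, triangle):
        p = node_topological_encodings(triangle)
        cols = dict(zip(NODE_TOPOLOGY_NAMES, p.T))
        assert np.allclose(cols["degree"], 2)
        assert np.allclose(cols["clustering"], 1.0)
        assert np.allclose(cols["k_core"], 2)
        assert np.allclose(cols["eccentricity"], 1)

    def test_path_closed_forms(self, path3):
        p = node_topological_encodings(path3)
        cols = dict(zip(NODE_TOPOLOGY_NAMES, p.T))
        assert cols["degree"].tolist() == [1, 2, 1]
        assert cols["eccentricity"].tolist() == [2, 1, 2]
        assert cols["k_core"].tolist() == [1, 1, 1]
        assert cols["betweenness"].tolist() == [0, 1, 0]

    def test_single_isolated_node(self):
        p = node_topological_encodings(make_graph(1, []))
        cols = dict(zip(NODE_TOPOLOGY_NAMES, p.T))
        assert cols["degree"][0] == 0
        assert cols["clustering"][0] == 0
        assert cols["pagerank"][0] == pytest.approx(1.0)


class TestEdgeTopology:
    def test_triangle_edge_values(self, triangle):
        g = edge_topological_encodings(triangle)
        assert g.shape == (6, 4)
        assert np.allclose(g[:, 1], 1.0 / 3.0)           # Jaccard
        assert np.allclose(g[:, 2], 1.0 / np.log(2.0))   # Adamic-Adar
        assert np.allclose(g[:, 3], 4.0)                 # pref. attachment

    def test_single_edge_graph(self, k2):
        g = edge_topological_encodings(k2)
        assert np.allclose(g[:, 1], 0.0)
        assert np.allclose(g[:, 3], 1.0)

    def test_rows_align_with_edge_storage(self, path3):
        g = edge_topological_encodings(path3)
        assert g.shape == (path3.num_edges, 4)
        # symmetric measure: both directions of an edge carry equal rows
        cols = {tuple(e): row for e, row in
                zip(path3.edge_index.T.tolist(), g)}
        assert np.array_equal(cols[(0, 1)], cols[(1, 0)])


class TestLaplacianPE:
    def test_p3_spectrum(self, path3):
        out = laplacian_pe(path3, 2)
        assert out is not None
        vecs, vals = out
        assert np.allclose(vals, [1.0, 3.0])
        # eigen residual against a dense reconstruction
        lap = np.diag([1, 2, 1]) - (np.eye(3, k=1) + np.eye(3, k=-1))
        for j in range(2):
            assert np.linalg.norm(lap @ vecs[:, j] - vals[j] * vecs[:, j]) <= 1e-8

    def test_k2_insufficient(self, k2):
        assert laplacian_pe(k2, 2) is None

    def test_columns_orthonormal(self, rng):
        g = random_connected_graph(9, rng)
        vecs, _ = laplacian_pe(g, 4)
        assert np.allclose(vecs.T @ vecs, np.eye(4), atol=1e-8)

    def test_sign_fixed_largest_entry_positive(self, rng):
        g = random_connected_graph(7, rng)
        vecs, _ = laplacian_pe(g, 3)
        for j in range(3):
            assert vecs[np.argmax(np.abs(vecs[:, j])), j] > 0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_zero_eigenvalues_count_components(self, seed):
        import scipy.linalg

        rng = np.random.default_rng(seed)
        a = random_connected_graph(5, rng)
        b = random_connected_graph(4, rng)
        pairs = np.concatenate([a.undirected_edges(),
                                b.undirected_edges() + 5])
        g = make_graph(9, pairs)
        adj = np.zeros((9, 9))
        for u, v in g.edge_index.T:
            adj[u, v] = 1
        w = scipy.linalg.eigh(np.diag(adj.sum(1)) - adj, eigvals_only=True)
        assert int(np.sum(np.abs(w) < 1e-8)) == 2


class TestStandardizer:
    def test_unit_variance_after_transform(self):
        stats = fit_standardizer([np.array([[1.0], [2.0], [3.0]])])
        out = apply_standardizer(np.array([[1.0], [2.0], [3.0]]), stats)
        assert abs(out.mean()) <= 1e-12
        assert abs(out.var(ddof=1) - 1.0) <= 1e-12

    def test_constant_column_flagged_and_zeroed(self):
        stats = fit_standardizer([np.full((3, 1), 5.0)])
        assert stats.constant[0]
        assert np.all(apply_standardizer(np.full((3, 1), 5.0), stats) == 0)

    def test_train_stats_applied_to_shifted_val(self):
        stats = fit_standardizer([np.array([[0.0], [2.0]])])
        val = apply_standardizer(np.array([[11.0]]), stats)
        assert val[0, 0] == pytest.approx((11.0 - 1.0) / np.sqrt(2.0))

    def test_empty_split_errors(self):
        with pytest.raises(ValueError):
            fit_standardizer([])


class TestFilterInvalid:
    def test_k2_discarded_for_insufficient_lpe(self, rng):
        graphs = [random_connected_graph(6, rng) for _ in range(9)]
        graphs.append(make_graph(2, [(0, 1)]))
        kept, bundles, log = filter_invalid(graphs, d_l=2)
        assert len(kept) == 9 and len(bundles) == 9
        assert log == [("", "insufficient LPE")]

    def test_all_finite_batch_is_identity(self, rng):
        graphs = [random_connected_graph(6, rng) for _ in range(4)]
        kept, _, log = filter_invalid(graphs, d_l=2)
        assert kept == graphs and log == []

    def test_missing_electron_affinity_discards(self, rng):
        g = random_connected_graph(5, rng)
        helium = make_graph(5, g.undirected_edges(), z=2)
        kept, _, log = filter_invalid([helium], d_l=2)
        assert kept == [] and log[0][1] == "non-finite CE"


class TestPermutationEquivariance:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bundle_rows_permute_with_nodes(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(8, rng)
        zs = rng.choice([1, 6, 7, 8], size=8)
        g = make_graph(8, g.undirected_edges(), z=zs)
        perm = rng.permutation(8)
        pairs = np.sort(np.stack([perm[g.undirected_edges()[:, 0]],
                                  perm[g.undirected_edges()[:, 1]]], axis=1),
                        axis=1)
        gp = make_graph(8, pairs, z=zs[np.argsort(perm)])
        b, _ = compute_bundle(g, 2)
        bp, _ = compute_bundle(gp, 2)
        inv = np.argsort(perm)
        for key in ("C", "P"):
            assert np.allclose(getattr(bp, key)[perm],
                               getattr(b, key), atol=1e-8)
        # edge rows re-align under the relabeling
        rows = {tuple(e): r for e, r in zip(gp.edge_index.T.tolist(), bp.G)}
        for e, r in zip(g.edge_index.T.tolist(), b.G):
            assert np.allclose(rows[(perm[e[0]], perm[e[1]])], r, atol=1e-8)
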