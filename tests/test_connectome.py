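import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.stats

from chd.connectome import (
    ConnectomeGraph,
    LongRangeEdges,
    average_graphs,
    build_adjacency,
    load_graph,
    prune_isolated,
    read_long_edges,
    save_graph,
    synth_connectome,
    write_long_edges,
)
from chd.connectome import _two_hemisphere_mesh
from chd.errors import InputError
from chd.mesh import SurfaceMesh, make_icosphere

from conftest import graph_from_edges


def single_triangle():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    return SurfaceMesh(vertices=verts, triangles=np.array([[0, 1, 2]]))


def no_long_edges():
    return LongRangeEdges(np.empty((0, 2), np.int64), provenance="synthetic")


class TestBuildAdjacency:
    def test_single_triangle_mesh_edges_only(self):
        g = build_adjacency(single_triangle(), no_long_edges())
        assert g.n_edges == 3
        assert g.adjacency.diagonal().sum() == 0

    def test_self_pair_rejected(self):
        with pytest.raises(InputError, match="self-pair"):
            build_adjacency(single_triangle(), LongRangeEdges([[0, 0]]))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(InputError, match="out of range"):
            build_adjacency(single_triangle(), LongRangeEdges([[0, 7]]))

    def test_empty_mesh_rejected(self):
        with pytest.raises(InputError):
            SurfaceMesh(vertices=np.empty((0, 3)), triangles=np.empty((0, 3), int))

    def test_icosphere_plus_seeded_long_pairs_vs_bruteforce_union(self):
        # oracle: explicit set union of mesh-edge pairs and long pairs
        mesh = make_icosphere(2)
        rng = np.random.default_rng(42)
        pairs = rng.choice(mesh.n_vertices, size=(50, 2), replace=True)
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        g = build_adjacency(mesh, LongRangeEdges(pairs))
        mesh_set = {tuple(e) for e in mesh.edges()}
        long_set = {tuple(sorted(p)) for p in pairs}
        union = mesh_set | long_set
        assert g.n_edges == len(union)
        assert g.n_edges == len(mesh_set) + len(long_set - mesh_set)
        # provenance partition: local + novel long = all edges
        assert len(g.local_edges) + len(g.long_edges) == g.n_edges

    def test_duplicate_long_pair_flagged_local(self):
        mesh = single_triangle()
        g = build_adjacency(mesh, LongRangeEdges([[0, 1]]))
        assert g.n_edges == 3
        assert len(g.long_edges) == 0


class TestAverageGraphs:
    def test_single_graph_identity(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        avg = average_graphs([g])
        assert (avg.adjacency != g.adjacency).nnz == 0

    def test_disjoint_edges_average_half(self):
        g1 = graph_from_edges(4, [(0, 1)])
        g2 = graph_from_edges(4, [(2, 3)])
        avg = average_graphs([g1, g2])
        dense = avg.adjacency.toarray()
        assert dense[0, 1] == 0.5 and dense[2, 3] == 0.5
        assert dense.sum() == 2.0

    def test_random_graphs_match_dense_mean_oracle(self):
        rng = np.random.default_rng(3)
        graphs = []
        dense = np.zeros((12, 12))
        for _ in range(5):
            iu = np.triu_indices(12, k=1)
            mask = rng.random(len(iu[0])) < 0.3
            edges = np.stack([iu[0][mask], iu[1][mask]], axis=1)
            g = graph_from_edges(12, edges)
            graphs.append(g)
            dense += g.adjacency.toarray()
        avg = average_graphs(graphs)
        np.testing.assert_allclose(avg.adjacency.toarray(), dense / 5, atol=1e-15)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(InputError, match="differ"):
            average_graphs(
                [graph_from_edges(3, [(0, 1)]), graph_from_edges(4, [(0, 1)])]
            )


class TestPruneIsolated:
    def test_no_isolates_unchanged(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        pruned = prune_isolated(g)
        assert pruned.n == 3
        np.testing.assert_array_equal(pruned.vertex_map, np.arange(3))

    def test_one_isolate_removed(self):
        g = graph_from_edges(4, [(0, 1), (1, 3)])  # vertex 2 isolated
        pruned = prune_isolated(g)
        assert pruned.n == 3
        np.testing.assert_array_equal(pruned.vertex_map, [0, 1, 3])

    def test_planted_isolates_vs_degree_scan_oracle(self):
        rng = np.random.default_rng(11)
        n = 40
        iu = np.triu_indices(n, k=1)
        mask = rng.random(len(iu[0])) < 0.1
        edges = np.stack([iu[0][mask], iu[1][mask]], axis=1)
        # plant isolates by deleting all edges touching chosen vertices
        planted = rng.choice(n, size=6, replace=False)
        keep = ~(np.isin(edges[:, 0], planted) | np.isin(edges[:, 1], planted))
        g = graph_from_edges(n, edges[keep])
        pruned = prune_isolated(g)
        deg = np.asarray(g.adjacency.sum(axis=1)).ravel()
        np.testing.assert_array_equal(pruned.vertex_map, np.flatnonzero(deg > 0))

    def test_all_isolated_rejected(self):
        g = ConnectomeGraph(adjacency=sp.csr_matrix((3, 3)))
        with pytest.raises(InputError, match="isolated"):
            prune_isolated(g)


class TestIcosphere:
    def test_order0_is_icosahedron(self):
        m = make_icosphere(0)
        assert m.n_vertices == 12
        assert m.n_triangles == 20

    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_vertex_count_and_euler_characteristic(self, order):
        m = make_icosphere(order)
        assert m.n_vertices == 10 * 4**order + 2
        assert m.euler_characteristic() == 2

    def test_negative_order_rejected(self):
        with pytest.raises(InputError):
            make_icosphere(-1)

    def test_order_above_maximum_rejected(self):
        with pytest.raises(InputError):
            make_icosphere(7)

    def test_unit_sphere(self):
        m = make_icosphere(2)
        np.testing.assert_allclose(np.linalg.norm(m.vertices, axis=1), 1.0)


class TestSynthConnectome:
    def test_zero_long_edges_gives_two_components(self):
        g = synth_connectome(1, 0, 0.5, seed=0)
        n_comp, _ = csgraph.connected_components(g.adjacency, directed=False)
        assert n_comp == 2

    def test_same_seed_bitwise_identical(self):
        g1 = synth_connectome(1, 40, 0.5, seed=5)
        g2 = synth_connectome(1, 40, 0.5, seed=5)
        assert (g1.adjacency != g2.adjacency).nnz == 0
        np.testing.assert_array_equal(g1.long_edges, g2.long_edges)

    def test_different_seed_differs(self):
        g1 = synth_connectome(1, 40, 0.5, seed=5)
        g2 = synth_connectome(1, 40, 0.5, seed=6)
        assert (g1.adjacency != g2.adjacency).nnz > 0

    def test_too_many_long_edges_rejected(self):
        with pytest.raises(InputError):
            synth_connectome(0, 10_000, 0.5, seed=0)

    def test_inter_hemisphere_fraction(self):
        g = synth_connectome(2, 200, 1.0, seed=3, inter_hemisphere_fraction=0.25)
        half = g.n // 2
        inter = ((g.long_edges[:, 0] < half) != (g.long_edges[:, 1] < half)).sum()
        assert inter == 50

    def test_long_edge_distances_match_decay_model_ks(self):
        # oracle: independent weighted resampling over the enumerated pair set
        decay = 0.5
        g = synth_connectome(2, 200, decay, seed=7, inter_hemisphere_fraction=0.0)
        mesh = _two_hemisphere_mesh(2, 2.5)
        coords = mesh.vertices
        half = mesh.n_vertices // 2
        sampled_d = np.linalg.norm(
            coords[g.long_edges[:, 0]] - coords[g.long_edges[:, 1]], axis=1
        )
        iu, ju = np.triu_indices(mesh.n_vertices, k=1)
        same_hemi = (iu < half) == (ju < half)
        forbidden = {tuple(e) for e in mesh.edges()}
        ok = same_hemi & np.array(
            [(a, b) not in forbidden for a, b in zip(iu, ju)]
        )
        iu, ju = iu[ok], ju[ok]
        d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        w = np.exp(-d / decay)
        rng = np.random.default_rng(123)
        idx = rng.choice(len(d), size=200, replace=False, p=w / w.sum())
        oracle_d = d[idx]
        stat = scipy.stats.ks_2samp(sampled_d, oracle_d)
        assert stat.pvalue > 0.01


class TestGraphInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetry_and_zero_diagonal(self, seed):
        g = synth_connectome(1, 30, 0.5, seed=seed)
        a = g.adjacency
        assert (a != a.T).nnz == 0
        assert a.diagonal().sum() == 0
        assert set(np.unique(a.data)) == {1.0}


class TestIO:
    def test_mtx_round_trip(self, tmp_path):
        g = synth_connectome(1, 20, 0.5, seed=2)
        path = tmp_path / "graph.mtx"
        save_graph(g, path)
        g2 = load_graph(path)
        assert (g.adjacency != g2.adjacency).nnz == 0

    def test_long_edges_tsv_round_trip(self, tmp_path):
        edges = LongRangeEdges([[0, 5], [2, 9]])
        path = tmp_path / "edges.tsv"
        write_long_edges(edges, 12, path)
        loaded, n = read_long_edges(path)
        assert n == 12
        np.testing.assert_array_equal(loaded.pairs, edges.pairs)

    @pytest.mark.parametrize("fmt", ["off", "ply"])
    def test_mesh_round_trip(self, tmp_path, fmt):
        from chd import mesh as mesh_io

        m = make_icosphere(1)
        path = tmp_path / f"m.{fmt}"
        getattr(mesh_io, f"write_{fmt}")(m, path)
        m2 = mesh_io.read_mesh(path)
        np.testing.assert_allclose(m2.vertices, m.vertices)
        np.testing.assert_array_equal(m2.triangles, m.triangles)

    def test_truncated_off_rejected(self, tmp_path):
        from chd.errors import FormatError
        from chd.mesh import read_off

        path = tmp_path / "bad.off"
        path.write_text("OFF\n10 5 0\n0 0 0\n")
        with pytest.raises(FormatError):
            read_off(path)
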