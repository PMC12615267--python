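"""Delaunay complex, edge filtering, terminal links, boundary operators."""

import numpy as np
import pytest

from conftest import random_small_complex
from hodgeflow import simplicial_complex as scx
from hodgeflow.synthetic_data import toy_complex


class TestDelaunayComplex:
    def test_minimal_triangle(self):
        sc = scx.delaunay_complex(np.array([[0.0, 0], [1, 0], [0, 1]]))
        assert sc.n_triangles == 1 and sc.n_edges == 3

    def test_square_two_triangles(self):
        sc = scx.delaunay_complex(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]))
        assert sc.n_triangles == 2 and sc.n_edges == 5

    def test_euler_characteristic_of_disc(self):
        rng = np.random.default_rng(0)
        pts = rng.random((50, 2))
        sc = scx.delaunay_complex(pts)
        assert 50 - sc.n_edges + sc.n_triangles == 1
        assert scx.betti1(sc) == 0

    def test_collinear_input_rejected(self):
        pts = np.c_[np.arange(5.0), np.zeros(5)]
        with pytest.raises(ValueError, match="collinear"):
            scx.delaunay_complex(pts)


class TestEdgeFiltering:
    def test_equal_lengths_nothing_removed(self):
        sc = scx.delaunay_complex(np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]))
        out = scx.filter_edges_quantile(sc)
        assert out.n_edges == sc.n_edges and out.n_triangles == sc.n_triangles

    def test_dumbbell_bridge_removed(self):
        rng = np.random.default_rng(1)
        left = rng.random((20, 2))
        right = rng.random((20, 2)) + [30.0, 0.0]
        sc = scx.delaunay_complex(np.vstack([left, right]))
        with pytest.warns(UserWarning, match="components"):
            out = scx.filter_edges_quantile(sc, factor=3, q=0.75)
        # every surviving edge stays within one blob
        sides = (out.edges < 20).all(axis=1) | (out.edges >= 20).all(axis=1)
        assert sides.all()

    def test_boundary_consistency_after_filter(self):
        rng = np.random.default_rng(2)
        sc = scx.delaunay_complex(rng.standard_normal((40, 2)))
        out = scx.filter_edges_quantile(sc, factor=1.2, q=0.5)
        b1, b2 = scx.boundary_matrices(out)
        assert (b1 @ b2).nnz == 0


class TestPh0Radius:
    def test_two_points(self):
        thr = scx.ph0_radius_threshold(np.array([[0.0, 0], [3.0, 0]]))
        assert np.isclose(thr.min_single_component_radius, 3.0)
        assert np.isclose(thr.threshold, 3.6)

    def test_three_points_on_line(self):
        thr = scx.ph0_radius_threshold(np.array([[0.0, 0], [1.0, 0], [5.0, 0]]))
        assert np.isclose(thr.min_single_component_radius, 4.0)
        assert np.isclose(thr.threshold, 4.8)

    def test_union_find_filtration_agrees_with_mst(self):
        # oracle: grow radius, union-find until one component
        rng = np.random.default_rng(3)
        pts = rng.random((100, 2))
        thr = scx.ph0_radius_threshold(pts, factor=1.0)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        pairs = [(d[i, j], i, j) for i in range(100) for j in range(i + 1, 100)]
        parent = list(range(100))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_comp, death = 100, 0.0
        for dist, i, j in sorted(pairs):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                n_comp -= 1
                death = dist
                if n_comp == 1:
                    break
        assert np.isclose(thr.min_single_component_radius, death)

    def test_radius_filter_keeps_single_component(self):
        rng = np.random.default_rng(4)
        pts = rng.random((60, 2))
        sc = scx.delaunay_complex(pts)
        thr = scx.ph0_radius_threshold(pts, factor=1.2)
        out = scx.filter_edges_radius(sc, thr.threshold)
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(out.adjacency(weighted=False))
        assert n_comp == 1


class TestBoundaryMatrices:
    def test_toy_reference_entries(self, toy_sc):
        b1, b2 = scx.boundary_matrices(toy_sc)
        b1, b2 = b1.toarray(), b2.toarray()
        # vertex/edge/triangle ids are 0-based here; fixture ids 1-based
        assert b1[0, 0] == -1  # edge (1,2) leaves vertex 1
        assert b1[1, 0] == +1  # edge (1,2) enters vertex 2
        e23 = toy_sc.edge_id(1, 2)
        e24 = toy_sc.edge_id(1, 3)
        assert b2[e23, 0] == +1  # (2,3) runs with triangle (2,3,4)
        assert b2[e24, 0] == -1  # (2,4) runs against triangle (2,3,4)
        # edge (1,2) bounds no triangle
        assert np.all(b2[toy_sc.edge_id(0, 1)] == 0)

    def test_boundary_of_boundary_zero_exactly(self, toy_sc):
        assert (toy_sc.B1 @ toy_sc.B2).nnz == 0

    def test_b2_columns_have_three_signed_entries(self, toy_sc):
        b2 = toy_sc.B2.toarray()
        assert b2.shape == (10, 3)
        for q in range(3):
            col = b2[:, q]
            assert sorted(np.abs(col[col != 0])) == [1, 1, 1]


class TestTrianglesFromEdges:
    def test_toy_fixture_cliques(self):
        toy = toy_complex()
        tris = scx.triangles_from_edges(np.array(toy.edges))
        assert tris == [(2, 3, 4), (2, 4, 5), (4, 6, 7)]

    def test_path_has_no_cliques(self):
        edges = np.array([(i, i + 1) for i in range(6)])
        assert scx.triangles_from_edges(edges) == []

    def test_k4_has_four_faces(self):
        edges = np.array([(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert len(scx.triangles_from_edges(edges)) == 4


class TestTerminalLinks:
    @pytest.mark.parametrize("n_arms,expected", [(1, 1), (2, 2), (3, 3)])
    def test_betti_matches_arm_count(self, n_arms, expected, request):
        # reuse the cached full fit for the bifurcation; cheap rebuilds otherwise
        import warnings

        from hodgeflow import RunConfig, fit_tree
        from hodgeflow.synthetic_data import gen_multifurcation_cloud

        cloud = gen_multifurcation_cloud(600, n_arms=n_arms, noise_sd=0.05, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_tree(
                cloud.points, [cloud.root_index], RunConfig(n_paths=300, seed=1)
            )
        assert len(res.terminal_groups) == expected
        assert scx.betti1(res.sc) == expected
        assert res.basis.h == expected

    def test_dummy_removal_restores_hole_free_disc(self, bifurcation_fit):
        sc = bifurcation_fit.sc
        stripped = scx.SimplicialComplex(
            n_vertices=sc.n_vertices,
            edges=sc.edges[~sc.dummy_edges],
            triangles=sc.triangles[~sc.dummy_triangles],
            layout=sc.layout,
        )
        assert scx.betti1(stripped) == 0

    def test_all_dummies_flagged_and_boundary_valid(self, bifurcation_fit):
        sc = bifurcation_fit.sc
        assert sc.dummy_edges.sum() > 0
        b1, b2 = scx.boundary_matrices(sc)
        assert (b1 @ b2).nnz == 0


class TestFindTerminalGroups:
    def test_two_clear_peaks_on_a_path(self):
        # potential rises to both ends of a path rooted at the centre
        n = 21
        edges = np.array([(i, i + 1) for i in range(n - 1)])
        pt = np.abs(np.arange(n) - 10) / 10.0
        groups = scx.find_terminal_groups(edges, pt, persistence=0.2)
        assert len(groups) == 2
        peaks = sorted(int(g[np.argmax(pt[g])]) for g in groups)
        assert peaks == [0, 20]

    def test_shallow_wiggle_absorbed(self):
        n = 30
        edges = np.array([(i, i + 1) for i in range(n - 1)])
        pt = np.linspace(0, 1, n)
        pt[20] += 0.005  # sub-threshold bump
        groups = scx.find_terminal_groups(edges, pt, persistence=0.01)
        assert len(groups) == 1

    def test_low_peaks_behind_root_dropped(self):
        n = 40
        edges = np.array([(i, i + 1) for i in range(n - 1)])
        pt = np.linspace(0, 1, n)
        pt[0] = 0.015  # local max inside the root noise shell
        pt[1] = 0.0
        groups = scx.find_terminal_groups(
            edges, pt, persistence=0.01, min_peak_pt=0.02
        )
        assert len(groups) == 1
        assert int(groups[0][np.argmax(pt[groups[0]])]) == n - 1


class TestRandomComplexProperties:
    def test_boundary_and_betti_on_many_random_complexes(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            sc = random_small_complex(rng)
            b1, b2 = scx.boundary_matrices(sc)
            assert (b1 @ b2).nnz == 0
            r1 = np.linalg.matrix_rank(b1.toarray()) if sc.n_edges else 0
            r2 = np.linalg.matrix_rank(b2.toarray()) if sc.n_triangles else 0
            assert scx.betti1(sc) == sc.n_edges - r1 - r2 >= 0
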