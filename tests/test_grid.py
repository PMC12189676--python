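"""Lattice construction: node placement, boundary detection, masking,
adjacency and connectivity refinement."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

import gridfate as gf
from gridfate.grid import ANGLE_DECIMALS, ANGLE_EPS, default_spine_points


def brute_force_boundary(X, spine_points):
    """Independent re-derivation of the angular boundary rule."""
    keep = set()
    for s in np.atleast_2d(spine_points):
        theta = np.round(
            np.arctan((s[0] - X[:, 0] + ANGLE_EPS) / (s[1] - X[:, 1] + ANGLE_EPS)),
            ANGLE_DECIMALS,
        )
        dist = np.sqrt(((X - s) ** 2).sum(axis=1))
        for ang in np.unique(theta):
            members = np.flatnonzero(theta == ang)
            keep.add(members[np.argmax(dist[members])])
    return np.array(sorted(keep))


class TestMakeGrid:
    def test_unit_square_n3_node_coords(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0], [0.3, 0.7]]))
        grid = gf.make_grid(emb, 3)
        assert grid.n_nodes == 9
        levels = {0.0, 0.5, 1.0}
        assert set(np.round(grid.node_coords[:, 0], 12)) == levels
        assert set(np.round(grid.node_coords[:, 1], 12)) == levels

    def test_n2_gives_corner_nodes(self):
        emb = gf.Embedding2D(np.array([[2.0, -1.0], [4.0, 1.0], [3.0, 0.0]]))
        grid = gf.make_grid(emb, 2)
        got = {tuple(c) for c in grid.node_coords}
        assert got == {(2.0, -1.0), (2.0, 1.0), (4.0, -1.0), (4.0, 1.0)}

    def test_node_count_is_n_squared(self):
        emb = gf.Embedding2D(np.random.default_rng(0).normal(size=(40, 2)))
        assert gf.make_grid(emb, 50).n_nodes == 2500

    @pytest.mark.parametrize(
        "coords",
        [np.array([[0.0, 0.0], [0.0, 1.0]]), np.array([[0.0, 0.5], [1.0, 0.5]])],
    )
    def test_degenerate_span_rejected(self, coords):
        with pytest.raises(ValueError, match="degenerate"):
            gf.make_grid(gf.Embedding2D(coords), 3)

    def test_n_below_2_rejected(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            gf.make_grid(emb, 1)


class TestBoundaryCells:
    def test_lone_angle_cells_are_boundary(self):
        # two cells at distinct angles from the spine point: each is the sole
        # (hence farthest) member of its angle bucket
        emb = gf.Embedding2D(
            np.array([[0.0, 0.0], [5.0, 0.0]]), cell_ids=("a", "b")
        )
        b = gf.detect_boundary_cells(emb, [[10.0, 10.0]])
        assert b.cell_indices.tolist() == [0, 1]

    def test_collinear_cells_keep_farther(self):
        # constructed so the guarded ratios are exactly equal (1/2 and 2/4):
        # same angle bucket, only the farther cell survives
        eps = 1e-6
        emb = gf.Embedding2D(np.array([[eps - 1, eps - 2], [eps - 2, eps - 4]]))
        b = gf.detect_boundary_cells(emb, [[0.0, 0.0]])
        assert b.cell_indices.tolist() == [1]

    def test_circle_all_cells_boundary_vs_oracle(self):
        # small radius keeps opposite points' guarded angles distinct after
        # rounding (the arctangent folds the circle onto (-pi/2, pi/2))
        n = 100
        ang = 2 * np.pi * np.arange(n) / n + 0.123
        r = 0.001
        X = r * np.column_stack([np.cos(ang), np.sin(ang)])
        emb = gf.Embedding2D(X)
        spine = [[0.0, 0.0]]
        got = gf.detect_boundary_cells(emb, spine).cell_indices
        oracle = brute_force_boundary(X, spine)
        np.testing.assert_array_equal(got, oracle)
        assert got.size == n  # all angles distinct: every cell is boundary

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(200, 2))
            emb = gf.Embedding2D(X)
            spine = default_spine_points(emb)
            got = gf.detect_boundary_cells(emb, spine).cell_indices
            np.testing.assert_array_equal(got, brute_force_boundary(X, spine))

    def test_empty_spine_rejected(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            gf.detect_boundary_cells(emb, np.empty((0, 2)))


class TestMaskGrid:
    @staticmethod
    def _setup(n=10, n_cells=120, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(n_cells, 2))
        emb = gf.Embedding2D(X)
        grid = gf.make_grid(emb, n)
        boundary = gf.detect_boundary_cells(emb, default_spine_points(emb))
        return emb, grid, boundary

    def test_huge_j_is_identity(self):
        emb, grid, boundary = self._setup()
        out = gf.mask_grid(grid, emb, boundary, default_spine_points(emb),
                           j=grid.n_nodes + 1)
        assert out.mapped.all()

    def test_far_corner_node_unmapped(self):
        # compact cloud in the unit square plus lone extreme cells at (3, 0)
        # and (0, 3); the empty corner (3, 3) holds the lattice node farthest
        # from the centroid, ranking beyond every boundary cell at j=0
        rng = np.random.default_rng(0)
        X = np.vstack([rng.uniform(0, 1, size=(150, 2)), [[3.0, 0.0], [0.0, 3.0]]])
        emb = gf.Embedding2D(X)
        grid = gf.make_grid(emb, 12)
        boundary = gf.detect_boundary_cells(emb, default_spine_points(emb))
        out = gf.mask_grid(grid, emb, boundary, [X.mean(axis=0)], j=0)
        far_node = np.argmin(np.linalg.norm(grid.node_coords - [3.0, 3.0], axis=1))
        assert not out.mapped[far_node]

    def test_matches_rank_oracle(self):
        emb, grid, boundary = self._setup()
        observers = default_spine_points(emb)
        j = 2
        out = gf.mask_grid(grid, emb, boundary, observers, j=j)
        # brute-force recomputation of the joint ranking rule
        expected = np.ones(grid.n_nodes, dtype=bool)
        B = emb.coords[boundary.cell_indices]
        for obs in observers:
            d_nodes = np.linalg.norm(grid.node_coords - obs, axis=1)
            d_cells = np.linalg.norm(B - obs, axis=1)
            joint = np.concatenate([d_nodes, d_cells])
            order = np.argsort(joint, kind="stable")
            rank = np.empty_like(order)
            rank[order] = np.arange(order.size)
            thr = rank[len(d_nodes):].max() + j
            expected &= ~(rank[: len(d_nodes)] > thr)
        np.testing.assert_array_equal(out.mapped, expected)

    def test_interior_nodes_retained(self):
        emb, grid, boundary = self._setup()
        out = gf.mask_grid(grid, emb, boundary, default_spine_points(emb), j=3)
        # nodes well inside the dense unit square stay mapped
        inner = np.all((grid.node_coords > 0.25) & (grid.node_coords < 0.75), axis=1)
        assert out.mapped[inner].all()

    def test_all_masked_is_an_error(self):
        emb, grid, _ = self._setup()
        # boundary "cells" all at the observer: every node outranks them
        fake = gf.BoundaryCells(cell_indices=np.array([0]))
        lone = gf.Embedding2D(np.array([[50.0, 50.0], [50.0, 50.0001]]))
        with pytest.raises(ValueError, match="every lattice node"):
            gf.mask_grid(grid, lone, fake, [[50.0, 50.0]], j=0)


class TestAdjacency:
    def test_full_3x3_degrees(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        grid = gf.build_adjacency(gf.make_grid(emb, 3))
        deg = grid.degrees()
        center = grid.node_id(1, 1)
        assert deg[center] == 8
        corners = [grid.node_id(r, c) for r in (0, 2) for c in (0, 2)]
        assert all(deg[c] == 3 for c in corners)

    def test_chebyshev_distance_2_not_adjacent(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        grid = gf.make_grid(emb, 4)
        grid.mapped[:] = False
        grid.mapped[[grid.node_id(0, 0), grid.node_id(0, 2)]] = True
        grid = gf.build_adjacency(grid)
        assert grid.adjacency[grid.node_id(0, 0), grid.node_id(0, 2)] == 0

    def test_symmetric_zero_diagonal_chebyshev_1(self):
        rng = np.random.default_rng(5)
        emb = gf.Embedding2D(rng.normal(size=(80, 2)))
        grid = gf.build_grid(emb, n=12, j=2)
        A = grid.adjacency
        assert (A != A.T).nnz == 0
        assert A.diagonal().sum() == 0
        coo = A.tocoo()
        cheb = np.abs(
            grid.lattice_pos[coo.row] - grid.lattice_pos[coo.col]
        ).max(axis=1)
        assert np.all(cheb == 1)
        assert grid.mapped[coo.row].all() and grid.mapped[coo.col].all()


class TestRefineBoundary:
    def test_full_3x3_boundary_is_ring(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        grid = gf.refine_boundary(gf.build_adjacency(gf.make_grid(emb, 3)))
        assert grid.boundary_nodes.size == 8
        assert grid.node_id(1, 1) not in grid.boundary_nodes

    def test_path_all_boundary(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        grid = gf.make_grid(emb, 5)
        grid.mapped[:] = False
        row0 = [grid.node_id(0, c) for c in range(5)]
        grid.mapped[row0] = True
        grid = gf.refine_boundary(gf.build_adjacency(grid))
        np.testing.assert_array_equal(np.sort(grid.boundary_nodes), np.sort(row0))

    def test_two_blobs_bridged_to_one_component(self):
        emb = gf.Embedding2D(np.array([[0.0, 0.0], [1.0, 1.0]]))
        grid = gf.make_grid(emb, 7)
        grid.mapped[:] = False
        for r in range(2):
            for c in range(2):
                grid.mapped[grid.node_id(r, c)] = True
                grid.mapped[grid.node_id(r + 5, c + 5)] = True
        grid = gf.refine_boundary(gf.build_adjacency(grid))
        idx = grid.mapped_nodes
        n_comp, _ = connected_components(grid.adjacency[idx][:, idx], directed=False)
        assert n_comp == 1

    def test_build_grid_invariants(self):
        rng = np.random.default_rng(11)
        emb = gf.Embedding2D(rng.normal(size=(150, 2)))
        grid = gf.build_grid(emb, n=15, j=3)
        assert grid.n_nodes == 225
        assert set(grid.boundary_nodes) <= set(grid.mapped_nodes)
        idx = grid.mapped_nodes
        n_comp, _ = connected_components(grid.adjacency[idx][:, idx], directed=False)
        assert n_comp == 1
        deg = grid.degrees()
        np.testing.assert_array_equal(
            np.sort(grid.boundary_nodes), np.flatnonzero(grid.mapped & (deg < 8))
        )
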