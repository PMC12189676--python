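"""Shared fixtures: small embeddings, grids and trained pipelines.

Everything is generated programmatically and seeded; the expensive Y-tree
pipeline is session-scoped so the acceptance-style tests share one run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gridfate as gf


@pytest.fixture()
def unit_square_cells() -> gf.Embedding2D:
    """A dense uniform cloud on [0, 1]^2 including the exact corners."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(0, 1, size=(200, 2))
    corners = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    return gf.Embedding2D(np.vstack([corners, pts]))


@pytest.fixture()
def full_grid_5(unit_square_cells) -> gf.MappedGrid:
    """Fully mapped 5x5 lattice over the unit square (no masking)."""
    grid = gf.make_grid(unit_square_cells, 5)
    grid = gf.build_adjacency(grid)
    grid = gf.refine_boundary(grid)
    return grid


@pytest.fixture(scope="session")
def ytree():
    """The 500-cell, 2-branch manifold used across modules (seed 0)."""
    return gf.make_branching_manifold(n_cells=500, n_branches=2, seed=0)


@pytest.fixture(scope="session")
def ytree_pipeline(ytree):
    """Grid, pseudotime, projection and per-cell pseudotime for the Y-tree."""
    emb = gf.Embedding2D(ytree.embedding)
    grid = gf.build_grid(emb, n=50, j=3)
    node_labels = gf.project_labels_to_grid(ytree.clusters, emb, grid)
    starts = gf.select_start(
        grid, emb, "trunk", labels=ytree.clusters, node_labels=node_labels, seed=0
    )
    psi = gf.compute_pseudotime(grid, starts)
    cgmap = gf.build_cell_grid_map(emb, grid, k=15)
    cell_psi = gf.grid_to_cells(psi.psi, cgmap)
    states = gf.build_states(grid, ytree.latent, emb, k=15)
    return dict(
        manifold=ytree,
        embedding=emb,
        grid=grid,
        node_labels=node_labels,
        psi=psi,
        cgmap=cgmap,
        cell_psi=cell_psi,
        states=states,
    )


@pytest.fixture(scope="session")
def ytree_intensities(ytree_pipeline):
    """Decision and contribution maps for both branches (tabular Q, seed 0)."""
    p = ytree_pipeline
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for branch in ("branch_0", "branch_1"):
            for mode in ("decision", "contribution"):
                out[(branch, mode)] = gf.lineage_intensity(
                    p["grid"],
                    p["psi"],
                    p["manifold"].latent,
                    p["embedding"],
                    p["cgmap"],
                    p["node_labels"],
                    target_clusters=branch,
                    start_clusters="trunk",
                    mode=mode,
                    agent_kind="q",
                    episodes=2000,
                    seed=0,
                    states=p["states"],
                    early_stop=False,
                )
    return out
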