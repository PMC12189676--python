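"""Bidirectional value transfer between cell space and grid space.

Continuous values move between cells and mapped lattice nodes through a
k-nearest-neighbour Gaussian kernel: for each query point the k nearest
targets are found, a local bandwidth is set to the variance of those k
distances, and normalized Gaussian weights produce an interpolated value.
Categorical labels move to the grid by plain nearest-neighbour assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .grid import Embedding2D, MappedGrid

__all__ = [
    "CellGridMap",
    "build_cell_grid_map",
    "project_labels_to_grid",
    "grid_to_cells",
    "cells_to_grid",
    "normalize_unit",
]

#: lower bound on the local distance variance; at the floor (all k distances
#: equal) the kernel degenerates to uniform weights 1/k
VARIANCE_FLOOR = 1e-12


class CellGridMap:
    """Bidirectional kNN index between cells and mapped grid nodes.

    Attributes
    ----------
    k : neighbour count (default 15).
    cell_to_grid_idx, cell_to_grid_w : ``(m, k)`` node ids / weights per cell.
    grid_to_cell_idx, grid_to_cell_w : ``(n_mapped, k)`` cell ids / weights
        per mapped node (rows aligned with ``mapped_nodes``).
    """

    def __init__(self, embedding: Embedding2D, grid: MappedGrid, k: int = 15):
        mapped = grid.mapped_nodes
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > mapped.size:
            raise ValueError(
                f"k={k} exceeds the number of mapped grid nodes ({mapped.size})"
            )
        k_cells = min(k, embedding.n_cells)
        self.k = k
        self.mapped_nodes = mapped
        X = embedding.coords
        G = grid.node_coords[mapped]

        nn_g = NearestNeighbors(n_neighbors=k).fit(G)
        d_cg, i_cg = nn_g.kneighbors(X)
        self.cell_to_grid_idx = mapped[i_cg]
        self.cell_to_grid_w = _gaussian_weights(d_cg)

        nn_c = NearestNeighbors(n_neighbors=k_cells).fit(X)
        d_gc, i_gc = nn_c.kneighbors(G)
        self.grid_to_cell_idx = i_gc
        self.grid_to_cell_w = _gaussian_weights(d_gc)


def _gaussian_weights(dist: np.ndarray) -> np.ndarray:
    """Row-wise Gaussian kernel weights from sorted kNN distances.

    The bandwidth is the per-row variance of the k distances, floored at
    ``VARIANCE_FLOOR``.  Weights are computed on squared distances shifted by
    the row minimum (a softmax-style stabilization), so a vanishing bandwidth
    yields a point mass on the nearest neighbour while exactly equal
    distances yield the uniform 1/k limit.
    """
    d2 = dist**2
    var = np.maximum(dist.var(axis=1, keepdims=True), VARIANCE_FLOOR)
    z = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * var))
    return z / z.sum(axis=1, keepdims=True)


def build_cell_grid_map(
    embedding: Embedding2D, grid: MappedGrid, k: int = 15
) -> CellGridMap:
    """Construct the bidirectional Gaussian kNN index (default ``k=15``)."""
    return CellGridMap(embedding, grid, k=k)


def project_labels_to_grid(
    labels, embedding: Embedding2D, grid: MappedGrid
) -> np.ndarray:
    """Assign each mapped node the label of its single nearest cell.

    Exact distance ties resolve to the lowest cell index.  Returns an object
    array over all ``n**2`` nodes; unmapped nodes get ``None``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != embedding.n_cells:
        raise ValueError("labels must cover all cells")
    mapped = grid.mapped_nodes
    out = np.full(grid.n_nodes, None, dtype=object)
    G = grid.node_coords[mapped]
    X = embedding.coords
    # explicit argmin (first index on ties) in manageable chunks
    chunk = max(1, 10_000_000 // max(X.shape[0], 1))
    for s in range(0, G.shape[0], chunk):
        block = G[s : s + chunk]
        d2 = ((block[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        out[mapped[s : s + chunk]] = labels[np.argmin(d2, axis=1)]
    return out


def grid_to_cells(
    values: np.ndarray,
    cgmap: CellGridMap,
    annotation_weight: np.ndarray | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Interpolate a per-node field onto cells.

    ``values`` must be defined (finite) on all mapped nodes, indexed over the
    full lattice.  Optionally multiplies each cell's value by
    ``log(annotation_weight)`` (weights must exceed 1 so the factor stays
    positive), and min-max normalizes to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    v = (values[cgmap.cell_to_grid_idx] * cgmap.cell_to_grid_w).sum(axis=1)
    if annotation_weight is not None:
        w = np.asarray(annotation_weight, dtype=float)
        if np.any(w <= 1.0):
            raise ValueError(
                "annotation weights must be > 1 (their log multiplies the "
                "projected value)"
            )
        v = v * np.log(w)
    if normalize:
        v = normalize_unit(v)
    return v


def cells_to_grid(data, cgmap: CellGridMap):
    """Interpolate per-cell features onto mapped nodes.

    ``data`` is a ``(cells, features)`` array or DataFrame; the result has
    one row per lattice node (NaN on unmapped nodes) and preserves DataFrame
    column names.
    """
    is_df = isinstance(data, pd.DataFrame)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    vals = (arr[cgmap.grid_to_cell_idx] * cgmap.grid_to_cell_w[..., None]).sum(axis=1)
    if is_df:
        return pd.DataFrame(vals, index=cgmap.mapped_nodes, columns=data.columns)
    return vals


def normalize_unit(values: np.ndarray) -> np.ndarray:
    """Affine map of min to 0 and max to 1; a constant vector maps to zeros."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("normalize_unit requires finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
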