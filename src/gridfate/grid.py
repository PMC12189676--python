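"""Masked lattice representation of a 2-D single-cell embedding.

A continuous 2-D embedding (typically UMAP) is discretized into an ``n x n``
regular lattice.  Lattice nodes falling outside the data's support are masked
out using an angular boundary-detection step followed by a rank-based
observer criterion; the surviving ("mapped") nodes are wired into an
8-connected grid graph whose boundary is the set of mapped nodes with fewer
than eight mapped neighbours.  The result is the state space on which
pseudotime and the fate-decision MDP are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Embedding2D",
    "MappedGrid",
    "BoundaryCells",
    "default_spine_points",
    "make_grid",
    "detect_boundary_cells",
    "mask_grid",
    "build_adjacency",
    "refine_boundary",
    "build_grid",
]

#: guard added to both coordinate differences before the arctangent ratio
ANGLE_EPS = 1e-6
#: decimal places used when grouping guarded arctangent angles
ANGLE_DECIMALS = 6


@dataclass(frozen=True)
class Embedding2D:
    """A cells x 2 embedding with cell identifiers.

    Parameters
    ----------
    coords
        Real matrix of shape ``(m, 2)``; finite, at least two distinct rows.
    cell_ids
        Sequence of ``m`` identifiers (auto-generated when omitted).
    """

    coords: np.ndarray
    cell_ids: tuple = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"embedding must be (cells, 2), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("embedding needs at least 2 cells")
        if not np.all(np.isfinite(coords)):
            raise ValueError("embedding contains non-finite values")
        if np.unique(coords, axis=0).shape[0] < 2:
            raise ValueError("embedding needs at least 2 distinct points")
        object.__setattr__(self, "coords", coords)
        ids = self.cell_ids
        if not len(ids):
            ids = tuple(f"cell_{i}" for i in range(coords.shape[0]))
        if len(ids) != coords.shape[0]:
            raise ValueError("cell_ids length does not match coords")
        object.__setattr__(self, "cell_ids", tuple(ids))

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class BoundaryCells:
    """Cells judged to lie on the data boundary.

    ``angles``/``distances`` hold, per spine point, the guarded-arctangent
    angle and Euclidean distance of every cell; ``cell_indices`` is the union
    over spine points of the farthest cell within each distinct angle bucket.
    """

    cell_indices: np.ndarray
    angles: list = field(default_factory=list)
    distances: list = field(default_factory=list)


@dataclass
class MappedGrid:
    """An n x n lattice over an embedding, masked to the data's support.

    Attributes
    ----------
    n
        Lattice resolution per axis; total node count is ``n**2``.
    node_coords
        ``(n**2, 2)`` embedding-space coordinates of every lattice node.
    lattice_pos
        ``(n**2, 2)`` integer ``(row, col)`` positions, row along y, col
        along x, 0-based.  Node id = ``row * n + col``.
    mapped
        Boolean flag per node.
    adjacency
        Sparse symmetric 0/1 matrix over all ``n**2`` nodes; edges only join
        mapped nodes at Chebyshev lattice distance 1.
    boundary_nodes
        Mapped nodes with fewer than 8 mapped neighbours (set by
        :func:`refine_boundary`).
    observer_margin_j
        The rank margin used during masking (bookkeeping).
    """

    n: int
    node_coords: np.ndarray
    lattice_pos: np.ndarray
    mapped: np.ndarray
    adjacency: sp.csr_matrix | None = None
    boundary_nodes: np.ndarray | None = None
    observer_margin_j: int | None = None

    def __post_init__(self):
        self._check()

    def _check(self):
        n2 = self.n * self.n
        assert self.node_coords.shape == (n2, 2)
        assert self.lattice_pos.shape == (n2, 2)
        assert self.mapped.shape == (n2,)
        if self.boundary_nodes is not None:
            assert np.all(self.mapped[self.boundary_nodes]), "boundary ⊄ mapped"

    @property
    def n_nodes(self) -> int:
        return self.n * self.n

    @property
    def mapped_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.mapped)

    def node_id(self, row: int, col: int) -> int:
        return row * self.n + col

    def degrees(self) -> np.ndarray:
        if self.adjacency is None:
            raise ValueError("adjacency not built")
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


def default_spine_points(embedding: Embedding2D) -> np.ndarray:
    """The four axis-extreme cells plus the coordinate-wise centroid.

    Deterministic, parameter-free reference points used both for angular
    boundary detection (spine) and for rank-based masking (observers).
    """
    X = embedding.coords
    pts = np.array(
        [
            X[np.argmax(X[:, 0])],
            X[np.argmin(X[:, 0])],
            X[np.argmax(X[:, 1])],
            X[np.argmin(X[:, 1])],
            X.mean(axis=0),
        ]
    )
    return pts


def make_grid(embedding: Embedding2D, n: int) -> MappedGrid:
    """Lay an ``n x n`` regular lattice over the embedding's bounding box.

    Node x-coordinates are ``n`` equally spaced values from the minimum to
    the maximum of the first embedding axis, likewise for y.  All nodes start
    mapped.
    """
    if n < 2:
        raise ValueError(f"lattice resolution n must be >= 2, got {n}")
    X = embedding.coords
    x_left, x_right = X[:, 0].min(), X[:, 0].max()
    y_bottom, y_top = X[:, 1].min(), X[:, 1].max()
    if x_right == x_left or y_top == y_bottom:
        raise ValueError(
            "degenerate embedding span: all x or all y coordinates are equal; "
            "a 2-D lattice cannot be constructed"
        )
    xs = np.linspace(x_left, x_right, n)
    ys = np.linspace(y_bottom, y_top, n)
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lattice_pos = np.column_stack([rows.ravel(), cols.ravel()])
    node_coords = np.column_stack([xs[lattice_pos[:, 1]], ys[lattice_pos[:, 0]]])
    return MappedGrid(
        n=n,
        node_coords=node_coords,
        lattice_pos=lattice_pos,
        mapped=np.ones(n * n, dtype=bool),
    )


def _guarded_angles(spine: np.ndarray, X: np.ndarray) -> np.ndarray:
    # arctan of (Δx + ε) / (Δy + ε); the ε guard keeps the ratio finite when
    # a cell shares a coordinate with the spine point
    num = spine[0] - X[:, 0] + ANGLE_EPS
    den = spine[1] - X[:, 1] + ANGLE_EPS
    return np.arctan(num / den)


def detect_boundary_cells(
    embedding: Embedding2D, spine_points: np.ndarray | list
) -> BoundaryCells:
    """Identify boundary cells by angular sweep from each spine point.

    From each spine point every cell gets a guarded arctangent angle (rounded
    to 6 decimals for bucketing) and a Euclidean distance; within each
    distinct angle bucket only the farthest cell is kept.  The result is the
    union over spine points.
    """
    spine_points = np.atleast_2d(np.asarray(spine_points, dtype=float))
    if spine_points.shape[0] < 1:
        raise ValueError("at least one spine point required")
    X = embedding.coords
    if X.shape[0] == 0:
        raise ValueError("empty embedding")
    keep: set[int] = set()
    all_angles, all_dists = [], []
    for s in spine_points:
        theta = np.round(_guarded_angles(s, X), ANGLE_DECIMALS)
        dist = np.linalg.norm(X - s, axis=1)
        all_angles.append(theta)
        all_dists.append(dist)
        # group by angle, keep argmax distance per group (first index on ties)
        order = np.lexsort((-dist, theta))
        theta_sorted = theta[order]
        is_first = np.ones(len(order), dtype=bool)
        is_first[1:] = theta_sorted[1:] != theta_sorted[:-1]
        keep.update(order[is_first].tolist())
    return BoundaryCells(
        cell_indices=np.array(sorted(keep), dtype=int),
        angles=all_angles,
        distances=all_dists,
    )


def mask_grid(
    grid: MappedGrid,
    embedding: Embedding2D,
    boundary: BoundaryCells,
    observers: np.ndarray | list,
    j: int = 3,
) -> MappedGrid:
    """Unmap lattice nodes lying outside the data's support.

    For each observer point, lattice nodes and boundary cells are ranked
    jointly by ascending distance from the observer (ties broken by insertion
    index, nodes before cells).  A node is removed when, for some observer,
    its rank exceeds the maximum rank of any boundary cell plus the margin
    ``j``: nodes that sit farther out than the data's own boundary.
    """
    observers = np.atleast_2d(np.asarray(observers, dtype=float))
    if observers.shape[0] < 1:
        raise ValueError("at least one observer point required")
    if j < 0:
        raise ValueError("margin j must be >= 0")
    X = embedding.coords
    B = X[boundary.cell_indices]
    G = grid.node_coords
    n_nodes = G.shape[0]
    mapped = grid.mapped.copy()
    for obs in observers:
        d_nodes = np.linalg.norm(G - obs, axis=1)
        d_cells = np.linalg.norm(B - obs, axis=1)
        joint = np.concatenate([d_nodes, d_cells])
        ranks = np.empty(len(joint), dtype=int)
        ranks[np.argsort(joint, kind="stable")] = np.arange(len(joint))
        threshold = ranks[n_nodes:].max() + j
        mapped &= ~(ranks[:n_nodes] > threshold)
    if not mapped.any():
        raise ValueError(
            "masking removed every lattice node; increase the margin j or "
            "the resolution n"
        )
    return MappedGrid(
        n=grid.n,
        node_coords=grid.node_coords,
        lattice_pos=grid.lattice_pos,
        mapped=mapped,
        observer_margin_j=j,
    )


def build_adjacency(grid: MappedGrid) -> MappedGrid:
    """Wire mapped nodes at Chebyshev lattice distance 1 (8-connectivity)."""
    n = grid.n
    mapped = grid.mapped
    idx = np.flatnonzero(mapped)
    pos = grid.lattice_pos[idx]
    rows, cols = [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    id_of = -np.ones(n * n, dtype=int)
    id_of[idx] = idx
    for dr, dc in offsets:
        r, c = pos[:, 0] + dr, pos[:, 1] + dc
        ok = (r >= 0) & (r < n) & (c >= 0) & (c < n)
        nbr = r[ok] * n + c[ok]
        src = idx[ok]
        sel = id_of[nbr] >= 0
        rows.append(src[sel])
        cols.append(nbr[sel])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n * n, n * n)
    )
    grid.adjacency = adj
    return grid


def _bresenham(p0: tuple, p1: tuple) -> list:
    """Integer lattice points on the straight line from p0 to p1 inclusive."""
    r0, c0 = p0
    r1, c1 = p1
    points = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dr - dc
    r, c = r0, c0
    while True:
        points.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return points


def refine_boundary(grid: MappedGrid) -> MappedGrid:
    """Ensure a single connected component, then mark grid-boundary nodes.

    While the mapped subgraph is disconnected, the closest lattice-position
    pair between the largest component and a minor component is found and the
    unmapped nodes on the straight lattice line (Bresenham) between them are
    re-mapped; adjacency is rebuilt and the check repeats.  Finally the
    boundary is the set of mapped nodes with fewer than 8 mapped neighbours.
    """
    if grid.adjacency is None:
        raise ValueError("build_adjacency must run before refine_boundary")
    for _ in range(grid.n * grid.n):
        idx = grid.mapped_nodes
        sub = grid.adjacency[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        if n_comp == 1:
            break
        sizes = np.bincount(labels)
        main = np.argmax(sizes)
        main_pos = grid.lattice_pos[idx[labels == main]]
        # nearest minor component by lattice distance to the main component
        best = None
        for comp in range(n_comp):
            if comp == main:
                continue
            comp_pos = grid.lattice_pos[idx[labels == comp]]
            d = np.linalg.norm(
                main_pos[:, None, :] - comp_pos[None, :, :], axis=2
            )
            i, k = np.unravel_index(np.argmin(d), d.shape)
            if best is None or d[i, k] < best[0]:
                best = (d[i, k], tuple(main_pos[i]), tuple(comp_pos[k]))
        _, p_main, p_comp = best
        line = _bresenham(p_main, p_comp)
        for r, c in line:
            grid.mapped[grid.node_id(r, c)] = True
        build_adjacency(grid)
    else:  # pragma: no cover - n² Bresenham repairs always suffice on a lattice
        raise RuntimeError("could not connect mapped grid into one component")
    deg = grid.degrees()
    grid.boundary_nodes = np.flatnonzero(grid.mapped & (deg < 8))
    grid._check()
    return grid


def build_grid(
    embedding: Embedding2D,
    n: int = 50,
    j: int = 3,
    spine_points: np.ndarray | None = None,
    observers: np.ndarray | None = None,
) -> MappedGrid:
    """Full lattice construction: make, mask, wire, refine.

    Defaults ``n=50`` and ``j=3`` balance resolution against the risk of
    masking artefacts.  Spine and observer points default to the four
    axis-extreme cells plus the centroid.
    """
    if spine_points is None:
        spine_points = default_spine_points(embedding)
    if observers is None:
        observers = spine_points
    grid = make_grid(embedding, n)
    boundary = detect_boundary_cells(embedding, spine_points)
    grid = mask_grid(grid, embedding, boundary, observers, j)
    grid = build_adjacency(grid)
    grid = refine_boundary(grid)
    return grid
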