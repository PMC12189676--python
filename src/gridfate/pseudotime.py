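"""Pseudotime assignment on the mapped lattice.

Every mapped node receives a pseudotime: the mean, over a set of root nodes,
of unit-weight shortest-path distances (Dijkstra), min-max normalized to
[0, 1].  When the mapped graph has several connected components, the
component holding the majority of roots is the main one; each secondary
component is anchored at its embedding-space closest point to the main
component and offset by the pseudotime already assigned there, so that
disconnected islands inherit a consistent temporal ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .grid import Embedding2D, MappedGrid

__all__ = ["StartSet", "PseudotimeField", "select_start", "compute_pseudotime"]


@dataclass
class StartSet:
    """Root nodes for pseudotime propagation."""

    nodes: np.ndarray
    mode: str = "single-cell"  # or "cluster"
    n_sample: int = 10

    def __post_init__(self):
        self.nodes = np.atleast_1d(np.asarray(self.nodes, dtype=int))
        if self.nodes.size == 0:
            raise ValueError("start set is empty")


@dataclass
class PseudotimeField:
    """Per-node pseudotime with provenance.

    ``psi`` is in [0, 1] on mapped nodes and NaN elsewhere; ``raw_distance``
    is the unnormalized shortest-path statistic (mean over roots in the main
    component, offset Dijkstra in secondary components); ``component_id``
    labels the connected component of each mapped node (-1 for unmapped);
    ``offsets`` maps secondary component id -> pseudotime offset.
    """

    psi: np.ndarray
    raw_distance: np.ndarray
    component_id: np.ndarray
    offsets: dict = field(default_factory=dict)
    degenerate: bool = False


def select_start(
    grid: MappedGrid,
    embedding: Embedding2D,
    root,
    labels=None,
    n_sample: int = 10,
    boundary_only: bool = True,
    node_labels: np.ndarray | None = None,
    seed: int = 0,
) -> StartSet:
    """Resolve a root cell or root cluster into lattice start nodes.

    Single-cell mode (``root`` is a cell id or index): the mapped node
    nearest the root cell in embedding coordinates.  Cluster mode (``root``
    is a cluster label present in ``labels``): up to ``n_sample`` nodes
    sampled (seeded, without replacement) from the mapped nodes carrying that
    cluster label, intersected with the grid boundary when ``boundary_only``.

    ``node_labels`` are per-node cluster labels (from
    :func:`gridfate.projection.project_labels_to_grid`); they are computed on
    the fly when omitted in cluster mode.
    """
    mapped_idx = grid.mapped_nodes
    if labels is not None and root in set(np.asarray(labels).tolist()):
        if node_labels is None:
            from .projection import project_labels_to_grid

            node_labels = project_labels_to_grid(np.asarray(labels), embedding, grid)
        node_labels = np.asarray(node_labels, dtype=object)
        candidates = mapped_idx[node_labels[mapped_idx] == root]
        if boundary_only:
            if grid.boundary_nodes is None:
                raise ValueError("grid boundary not refined; run refine_boundary")
            candidates = np.intersect1d(candidates, grid.boundary_nodes)
        if candidates.size == 0:
            raise ValueError(
                f"no candidate start nodes for cluster {root!r}; "
                "try boundary_only=False"
            )
        rng = np.random.default_rng(seed)
        take = min(n_sample, candidates.size)
        nodes = rng.choice(candidates, size=take, replace=False)
        return StartSet(nodes=np.sort(nodes), mode="cluster", n_sample=n_sample)
    # single-cell mode
    ids = list(embedding.cell_ids)
    if root in ids:
        ci = ids.index(root)
    elif isinstance(root, (int, np.integer)) and 0 <= root < embedding.n_cells:
        ci = int(root)
    else:
        raise ValueError(f"root {root!r} is neither a known cell nor a cluster label")
    d = np.linalg.norm(grid.node_coords[mapped_idx] - embedding.coords[ci], axis=1)
    return StartSet(nodes=np.array([mapped_idx[np.argmin(d)]]), mode="single-cell")


def compute_pseudotime(grid: MappedGrid, starts: StartSet) -> PseudotimeField:
    """Propagate pseudotime from the start set over the mapped graph.

    All lattice edges have unit weight, so Dijkstra reduces to breadth-first
    distance.  The raw statistic on the main component is the mean over start
    nodes of their shortest-path distances; secondary components get an
    anchored, offset Dijkstra fill.  The final field is min-max normalized;
    a constant field (e.g. symmetric start placement on a tiny graph)
    normalizes to all zeros with a warning.
    """
    if grid.adjacency is None:
        raise ValueError("grid adjacency not built")
    start_nodes = starts.nodes
    if not np.all(grid.mapped[start_nodes]):
        raise ValueError("start nodes must be mapped")
    n2 = grid.n_nodes
    idx = grid.mapped_nodes
    sub = grid.adjacency[idx][:, idx].astype(float)
    n_comp, labels = connected_components(sub, directed=False)

    component_id = -np.ones(n2, dtype=int)
    component_id[idx] = labels

    start_comp = component_id[start_nodes]
    counts = np.bincount(start_comp, minlength=n_comp)
    top = counts.max()
    majority = np.flatnonzero(counts == top)
    if majority.size > 1:
        sizes = np.bincount(labels)[majority]
        main = int(majority[np.argmax(sizes)])
        warnings.warn(
            "start nodes split evenly across components; main component "
            "chosen as the largest one",
            stacklevel=2,
        )
    else:
        main = int(majority[0])

    pos_in_sub = -np.ones(n2, dtype=int)
    pos_in_sub[idx] = np.arange(idx.size)

    raw = np.full(n2, np.nan)
    # main component: mean of per-start Dijkstra distances
    main_starts = start_nodes[start_comp == main]
    if main_starts.size == 0:  # pragma: no cover - majority rule guarantees >= 1
        raise ValueError("no start node lies in the main component")
    dmat = dijkstra(sub, directed=False, indices=pos_in_sub[main_starts])
    dbar = np.atleast_2d(dmat).mean(axis=0)
    in_main = labels == main
    raw[idx[in_main]] = dbar[in_main]

    offsets: dict[int, float] = {}
    for comp in range(n_comp):
        if comp == main:
            continue
        comp_nodes = idx[labels == comp]
        main_nodes = idx[in_main]
        # anchor: embedding-space closest pair between the two components
        d = np.linalg.norm(
            grid.node_coords[main_nodes][:, None, :]
            - grid.node_coords[comp_nodes][None, :, :],
            axis=2,
        )
        i_main, i_comp = np.unravel_index(np.argmin(d), d.shape)
        tau = raw[main_nodes[i_main]]
        offsets[comp] = float(tau)
        d_comp = dijkstra(
            sub, directed=False, indices=pos_in_sub[comp_nodes[i_comp]]
        )
        sel = labels == comp
        raw[idx[sel]] = d_comp[sel] + tau

    psi = np.full(n2, np.nan)
    vals = raw[idx]
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        warnings.warn(
            "pseudotime field is constant; normalized to all zeros", stacklevel=2
        )
        psi[idx] = 0.0
        degenerate = True
    else:
        psi[idx] = (vals - lo) / (hi - lo)
        degenerate = False
    return PseudotimeField(
        psi=psi,
        raw_distance=raw,
        component_id=component_id,
        offsets=offsets,
        degenerate=degenerate,
    )
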