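"""The mapped lattice as an episodic Markov decision process.

States are lattice nodes carrying the mean latent vector of their k nearest
cells; actions are the 8 compass moves; rewards encode lineage targets
(cluster labels, "discrete") or gene programs (projected expression,
"continuous"), modulated by pseudotime in one of two modes:

* ``decision`` — reward weight ``exp(-beta * psi)`` decays along pseudotime,
  emphasizing early commitment signals;
* ``contribution`` — weight ``1 - exp(-beta * psi)`` grows along pseudotime,
  emphasizing cumulative lineage output.

The two weights are complementary and sum to 1 at every pseudotime.
Episodes start on nodes of the start clusters and end on leaving the mapped
region (reward -1), on reaching a grid-boundary node outside the start
region, on revisiting a node of the episode's own trajectory, or after
``t_max`` steps.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .grid import Embedding2D, MappedGrid
from .pseudotime import PseudotimeField

__all__ = [
    "ACTIONS",
    "ACTION_DELTAS",
    "action_target",
    "build_states",
    "RewardSpec",
    "Transition",
    "ReplayBuffer",
    "discrete_reward",
    "continuous_reward",
    "GridEnv",
]

#: compass actions in canonical order
ACTIONS = ("R", "RT", "T", "LT", "L", "LB", "B", "RB")

#: (d_row, d_col) for each action; row grows along y, col along x
ACTION_DELTAS = {
    "R": (0, 1),
    "RT": (1, 1),
    "T": (1, 0),
    "LT": (1, -1),
    "L": (0, -1),
    "LB": (-1, -1),
    "B": (-1, 0),
    "RB": (-1, 1),
}

_DELTA_ARRAY = np.array([ACTION_DELTAS[a] for a in ACTIONS])


def action_target(pos: tuple, action) -> tuple:
    """Lattice position reached by taking ``action`` from ``pos``.

    ``action`` may be a compass name or an index into :data:`ACTIONS`.
    Off-lattice results are returned as-is; bounds are the caller's concern.
    """
    if isinstance(action, (int, np.integer)):
        action = ACTIONS[action]
    dr, dc = ACTION_DELTAS[action]
    return (pos[0] + dr, pos[1] + dc)


def build_states(
    grid: MappedGrid, latent: np.ndarray, embedding: Embedding2D, k: int = 15
) -> np.ndarray:
    """Per-node state vectors: mean latent row of the k nearest cells.

    Returns an ``(n**2, d)`` array, NaN on unmapped nodes.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape[0] != embedding.n_cells:
        raise ValueError("latent must have one row per cell")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > embedding.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({embedding.n_cells})")
    mapped = grid.mapped_nodes
    nn = NearestNeighbors(n_neighbors=k).fit(embedding.coords)
    _, idx = nn.kneighbors(grid.node_coords[mapped])
    out = np.full((grid.n_nodes, latent.shape[1]), np.nan)
    out[mapped] = latent[idx].mean(axis=1)
    return out


@dataclass
class RewardSpec:
    """Reward configuration for lineage (discrete) or gene (continuous) runs.

    ``beta`` is the exponential decay rate of the pseudotime weight (default
    1.0: unit decay over the normalized pseudotime range).
    """

    mode: str  # "decision" | "contribution"
    kind: str = "discrete"  # "discrete" | "continuous"
    beta: float = 1.0
    start_clusters: tuple = ()
    end_clusters: tuple = ()
    reward_genes: tuple = ()
    punish_genes: tuple = ()

    def __post_init__(self):
        if self.mode not in ("decision", "contribution"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown reward kind {self.kind!r}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.kind == "discrete" and not self.end_clusters:
            raise ValueError("discrete rewards require non-empty end_clusters")
        if self.kind == "continuous" and not self.reward_genes:
            raise ValueError("continuous rewards require non-empty reward_genes")
        self.start_clusters = tuple(self.start_clusters)
        self.end_clusters = tuple(self.end_clusters)
        self.reward_genes = tuple(self.reward_genes)
        self.punish_genes = tuple(self.punish_genes)

    def weight(self, psi_next: float) -> float:
        """Pseudotime modulation weight for this mode."""
        w_dec = float(np.exp(-self.beta * psi_next))
        return w_dec if self.mode == "decision" else 1.0 - w_dec


@dataclass
class Transition:
    state: int
    action: int
    reward: float
    next_state: int
    done: bool

    def __post_init__(self):
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")


class ReplayBuffer:
    """FIFO experience buffer with a minimum-fill sampling guard.

    Uniform sampling with replacement is allowed only once the buffer holds
    at least ``min_fill_fraction * capacity`` transitions.
    """

    def __init__(self, capacity: int = 10_000, min_fill_fraction: float = 0.1):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.min_fill_fraction = min_fill_fraction
        self._store: deque = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._store)

    def push(self, tr: Transition) -> None:
        self._store.append(tr)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list:
        need = self.min_fill_fraction * self.capacity
        if len(self._store) < need:
            raise ValueError(
                f"buffer holds {len(self._store)} transitions; sampling "
                f"requires at least {need:.0f}"
            )
        picks = rng.integers(0, len(self._store), size=batch_size)
        return [self._store[i] for i in picks]


def discrete_reward(
    next_node: int | None,
    spec: RewardSpec,
    psi: PseudotimeField,
    node_labels: np.ndarray,
    delta_t: float = 0.0,
) -> float:
    """Cluster-annotation reward for arriving at ``next_node``.

    ``next_node is None`` encodes a move off the mapped grid (-1).  Landing
    on a node labelled with a target cluster pays the mode weight at that
    node's pseudotime plus the pseudotime progression bonus ``delta_t``;
    any other mapped node pays 0.
    """
    if next_node is None:
        return -1.0
    if node_labels[next_node] in spec.end_clusters:
        return spec.weight(float(psi.psi[next_node])) + delta_t
    return 0.0


def continuous_reward(
    next_node: int | None,
    spec: RewardSpec,
    psi: PseudotimeField,
    projected_expr: pd.DataFrame,
) -> float:
    """Projected-expression reward for arriving at ``next_node``.

    The mean projected expression of the reward genes at the node is scaled
    by the mode weight; punish genes subtract their mean scaled by the
    complementary weight.  ``next_node is None`` encodes a move off the
    mapped grid (-1).
    """
    missing = [
        g
        for g in (*spec.reward_genes, *spec.punish_genes)
        if g not in projected_expr.columns
    ]
    if missing:
        raise KeyError(f"genes not found in projected expression: {missing}")
    if next_node is None:
        return -1.0
    w_reward = spec.weight(float(psi.psi[next_node]))
    r_bar = float(projected_expr.loc[next_node, list(spec.reward_genes)].mean())
    reward = w_reward * r_bar
    if spec.punish_genes:
        p_bar = float(projected_expr.loc[next_node, list(spec.punish_genes)].mean())
        reward -= (1.0 - w_reward) * p_bar
    return reward


class GridEnv:
    """Episodic MDP over the mapped lattice.

    Parameters
    ----------
    grid, psi
        The mapped lattice and its pseudotime field.
    states
        ``(n**2, d)`` latent state vectors from :func:`build_states`.
    spec
        Reward configuration.
    node_labels
        Per-node cluster labels (required for discrete rewards and for the
        start region).
    projected_expr
        Nodes x genes DataFrame (required for continuous rewards).
    t_max
        Episode truncation horizon; defaults to ``10 * n``.
    episode_starts
        ``"start_clusters"`` (default): episodes begin uniformly on nodes of
        the start clusters.  ``"all"``: exploring starts over every mapped
        node, so value estimates receive updates across the whole lattice;
        the start-cluster region still defines where boundary contact does
        not terminate an episode.
    """

    def __init__(
        self,
        grid: MappedGrid,
        psi: PseudotimeField,
        states: np.ndarray,
        spec: RewardSpec,
        node_labels: np.ndarray | None = None,
        projected_expr: pd.DataFrame | None = None,
        t_max: int | None = None,
        seed: int = 0,
        episode_starts: str = "start_clusters",
    ):
        if grid.boundary_nodes is None:
            raise ValueError("grid boundary not refined")
        if spec.kind == "discrete" and node_labels is None:
            raise ValueError("discrete rewards require node_labels")
        if spec.kind == "continuous" and projected_expr is None:
            raise ValueError("continuous rewards require projected expression")
        self.grid = grid
        self.psi = psi
        self.states = states
        self.spec = spec
        self.node_labels = node_labels
        self.projected_expr = projected_expr
        self.t_max = 10 * grid.n if t_max is None else t_max
        self.rng = np.random.default_rng(seed)

        self._mapped_set = set(grid.mapped_nodes.tolist())
        self._boundary_set = set(grid.boundary_nodes.tolist())
        if node_labels is not None and spec.start_clusters:
            m = grid.mapped_nodes
            lab = np.asarray(node_labels, dtype=object)
            start_region = m[np.isin(lab[m], list(spec.start_clusters))]
        else:
            start_region = grid.mapped_nodes
        if episode_starts not in ("start_clusters", "all"):
            raise ValueError(f"unknown episode_starts {episode_starts!r}")
        self.start_nodes = (
            grid.mapped_nodes if episode_starts == "all" else start_region
        )
        self._start_region = start_region
        if self.start_nodes.size == 0:
            raise ValueError(
                f"no mapped nodes carry start clusters {spec.start_clusters}"
            )
        self._start_set = set(self._start_region.tolist())
        self._node = None
        self._history: list[int] = []
        self._steps = 0
        self._done = True

    @property
    def current_node(self) -> int | None:
        return self._node

    def state_vector(self, node: int) -> np.ndarray:
        return self.states[node]

    def reset(self, start_node: int | None = None) -> int:
        """Begin an episode on a start-cluster node (uniform when unset)."""
        if start_node is None:
            start_node = int(self.rng.choice(self.start_nodes))
        elif not self.grid.mapped[start_node]:
            raise ValueError(f"start node {start_node} is not mapped")
        self._node = int(start_node)
        self._history = [self._node]
        self._steps = 0
        self._done = False
        return self._node

    def _reward(self, next_node: int | None, cur: int) -> float:
        if self.spec.kind == "discrete":
            if next_node is None:
                dt = 0.0
            else:
                dt = float(self.psi.psi[next_node] - self.psi.psi[cur])
            return discrete_reward(next_node, self.spec, self.psi, self.node_labels, dt)
        return continuous_reward(next_node, self.spec, self.psi, self.projected_expr)

    def step(self, action) -> Transition:
        """Take a compass action; returns the transition and advances."""
        if self._done:
            raise RuntimeError("step() called on a terminated episode; reset() first")
        if isinstance(action, (int, np.integer)):
            a_idx = int(action)
        else:
            a_idx = ACTIONS.index(action)
        cur = self._node
        r, c = self.grid.lattice_pos[cur]
        nr, nc = action_target((r, c), a_idx)
        n = self.grid.n
        off = not (0 <= nr < n and 0 <= nc < n)
        nxt = None if off else self.grid.node_id(nr, nc)
        if nxt is not None and nxt not in self._mapped_set:
            nxt = None
        reward = self._reward(nxt, cur)
        self._steps += 1
        if nxt is None:
            done = True
            next_state = cur  # terminal bootstrap is masked by done
        else:
            done = (
                (nxt in self._boundary_set and nxt not in self._start_set)
                or (nxt in self._history)
                or (self._steps >= self.t_max)
            )
            next_state = nxt
            self._history.append(nxt)
            self._node = nxt
        self._done = done
        return Transition(
            state=cur, action=a_idx, reward=float(reward), next_state=next_state, done=done
        )
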