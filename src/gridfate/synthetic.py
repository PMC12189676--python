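"""Seeded synthetic fixtures: branching manifolds and toy gridworlds.

The branching manifold emulates the geometry a 2-D embedding of a
differentiation process provides: a common trunk with straight branches
radiating from its endpoint at equal angles, a per-cell ground-truth
progression in [0, 1], branch-specific latent components, and one marker
gene per branch whose expression ramps up monotonically after the branch
point.  The toy gridworld is a fully mapped lattice MDP with a single
terminal reward and a bundled value-iteration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import ACTIONS, ACTION_DELTAS

__all__ = [
    "SyntheticManifold",
    "make_branching_manifold",
    "ToyGridworld",
    "make_toy_gridworld",
    "value_iteration",
]

TRUNK_FRACTION = 0.4  # share of progression spent on the trunk


@dataclass
class SyntheticManifold:
    """A branching 2-D manifold with latent, expression and labels.

    ``clusters`` are ``"trunk"`` and ``"branch_0"`` ... ``"branch_{B-1}"``;
    marker gene ``gene_b`` ramps with progression along branch ``b``.
    """

    embedding: np.ndarray  # (cells, 2)
    latent: np.ndarray  # (cells, n_branches + 1)
    expression: pd.DataFrame  # (cells, genes)
    clusters: np.ndarray  # per-cell labels
    true_time: np.ndarray  # per-cell progression in [0, 1]
    branch_of: np.ndarray  # branch index, -1 on the trunk
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.embedding.shape[0]

    @property
    def marker_genes(self) -> list:
        return [c for c in self.expression.columns if c.startswith("marker_")]


def make_branching_manifold(
    n_cells: int = 500,
    n_branches: int = 2,
    n_genes: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticManifold:
    """Generate a trunk-plus-branches manifold.

    Cells are placed uniformly along total arclength; progression before
    ``TRUNK_FRACTION`` lies on the trunk, after it on one of ``n_branches``
    straight branches fanned over a 120-degree sector.  The embedding adds
    isotropic Gaussian jitter of ``noise_sd`` (embedding units; total extent
    is about 1).  Latent component ``b + 1`` loads on branch ``b`` and ramps
    with progression; component 0 is the trunk/primitive loading.  Marker
    gene ``marker_b`` is ``max(0, true_time - branch_onset)`` plus noise;
    the remaining genes are pure noise.
    """
    if n_branches < 2:
        raise ValueError("need at least 2 branches")
    if n_cells < 10 * n_branches:
        raise ValueError(f"need at least {10 * n_branches} cells for "
                         f"{n_branches} branches")
    if n_genes < n_branches:
        raise ValueError("need at least one gene per branch")
    rng = np.random.default_rng(seed)

    t = rng.uniform(0.0, 1.0, size=n_cells)
    on_trunk = t < TRUNK_FRACTION
    branch = np.where(on_trunk, -1, rng.integers(0, n_branches, size=n_cells))

    # trunk along +x from the origin; branches fan out from the trunk tip
    angles = np.linspace(-np.pi / 3, np.pi / 3, n_branches)
    pos = np.zeros((n_cells, 2))
    pos[on_trunk, 0] = t[on_trunk]
    tip = np.array([TRUNK_FRACTION, 0.0])
    for b in range(n_branches):
        sel = branch == b
        arm = t[sel] - TRUNK_FRACTION
        direction = np.array([np.cos(angles[b]), np.sin(angles[b])])
        pos[sel] = tip + arm[:, None] * direction
    embedding = pos + rng.normal(0.0, noise_sd, size=pos.shape)

    latent = np.zeros((n_cells, n_branches + 1))
    latent[:, 0] = np.maximum(0.0, 1.0 - t / TRUNK_FRACTION)
    for b in range(n_branches):
        sel = branch == b
        latent[sel, b + 1] = t[sel] - TRUNK_FRACTION
    latent += rng.normal(0.0, noise_sd, size=latent.shape)

    expr = np.zeros((n_cells, n_genes))
    for b in range(n_branches):
        ramp = np.where(branch == b, np.maximum(0.0, t - TRUNK_FRACTION), 0.0)
        expr[:, b] = ramp
    expr[:, :n_branches] += np.where(
        expr[:, :n_branches] > 0,
        rng.normal(0.0, noise_sd, size=(n_cells, n_branches)),
        0.0,
    )
    expr[:, n_branches:] = np.abs(
        rng.normal(0.0, noise_sd, size=(n_cells, n_genes - n_branches))
    )
    genes = [f"marker_{b}" for b in range(n_branches)] + [
        f"noise_{i}" for i in range(n_genes - n_branches)
    ]
    clusters = np.where(
        on_trunk, "trunk", np.char.add("branch_", branch.astype(str))
    ).astype(object)
    return SyntheticManifold(
        embedding=embedding,
        latent=latent,
        expression=pd.DataFrame(expr, columns=genes),
        clusters=clusters,
        true_time=t,
        branch_of=branch,
        seed=seed,
    )


class ToyGridworld:
    """Fully mapped ``size x size`` lattice MDP with one terminal reward.

    Dynamics: the 8 compass moves; stepping off the lattice is terminal with
    reward -1; entering the goal cell is terminal with the goal reward;
    every other move pays 0 and continues.  States are cell ids
    ``row * size + col``.
    """

    def __init__(self, size: int, reward_node: int, reward: float = 1.0):
        if size < 2:
            raise ValueError("size must be >= 2")
        if not 0 <= reward_node < size * size:
            raise ValueError("reward node outside the lattice")
        self.size = size
        self.reward_node = reward_node
        self.reward = reward
        self.n_states = size * size

    def step(self, state: int, action: int) -> tuple[int, float, bool]:
        """(next_state, reward, done); off-grid keeps the state index."""
        r, c = divmod(state, self.size)
        a = ACTIONS[action] if isinstance(action, (int, np.integer)) else action
        dr, dc = ACTION_DELTAS[a]
        nr, nc = r + dr, c + dc
        if not (0 <= nr < self.size and 0 <= nc < self.size):
            return state, -1.0, True
        nxt = nr * self.size + nc
        if nxt == self.reward_node:
            return nxt, self.reward, True
        return nxt, 0.0, False


def value_iteration(
    world: ToyGridworld, gamma: float = 0.9, tol: float = 1e-12,
    max_iter: int = 100_000
) -> tuple[np.ndarray, np.ndarray]:
    """Exact optimal values for the toy gridworld (the oracle).

    Returns ``(V, Q)`` with ``Q`` of shape ``(states, 8)``; the goal state is
    absorbing with value 0 (the reward is paid on entry).
    """
    n = world.n_states
    Q = np.zeros((n, len(ACTIONS)))
    for _ in range(max_iter):
        V = Q.max(axis=1)
        V[world.reward_node] = 0.0
        Q_new = np.empty_like(Q)
        for s in range(n):
            for a in range(len(ACTIONS)):
                nxt, r, done = world.step(s, a)
                Q_new[s, a] = r + (0.0 if done else gamma * V[nxt])
        if np.abs(Q_new - Q).max() < tol:
            Q = Q_new
            break
        Q = Q_new
    V = Q.max(axis=1)
    V[world.reward_node] = 0.0
    return V, Q


def make_toy_gridworld(size: int, reward_node: int, reward: float = 1.0) -> ToyGridworld:
    """Construct the toy lattice MDP fixture."""
    return ToyGridworld(size, reward_node, reward=reward)
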