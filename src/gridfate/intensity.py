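"""Fate decision and contribution intensity maps, plus downstream analyses.

An intensity map is the critic's state value over the lattice after training
under a given reward mode, projected back onto cells and normalized to
[0, 1].  Decision maps (rewards decaying along pseudotime) peak where early
commitment signals concentrate; contribution maps (rewards growing along
pseudotime) peak where cumulative lineage output concentrates.  The
intensity-weighted mean pseudotime compares the two: on a given lineage the
decision map's weighted pseudotime precedes the contribution map's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import Policy, TrainingTrace, train
from .env import GridEnv, RewardSpec, build_states
from .grid import Embedding2D, MappedGrid
from .projection import CellGridMap, cells_to_grid, grid_to_cells, normalize_unit
from .pseudotime import PseudotimeField

__all__ = [
    "IntensityMap",
    "lineage_intensity",
    "gene_intensity",
    "weighted_pseudotime",
    "binned_profile",
    "select_branch_markers",
    "rollout_trajectory",
]


@dataclass
class IntensityMap:
    """Per-node and per-cell state values from a trained critic."""

    node_values: np.ndarray  # (n**2,), NaN on unmapped nodes
    cell_values: np.ndarray  # (cells,), min-max normalized to [0, 1]
    mode: str
    spec: RewardSpec
    trace: TrainingTrace
    policy: Policy


def _train_intensity(
    grid: MappedGrid,
    psi: PseudotimeField,
    states: np.ndarray,
    spec: RewardSpec,
    cgmap: CellGridMap,
    node_labels: np.ndarray | None,
    projected_expr: pd.DataFrame | None,
    agent_kind: str,
    episodes: int,
    seed: int,
    **train_kw,
) -> IntensityMap:
    env = GridEnv(
        grid,
        psi,
        states,
        spec,
        node_labels=node_labels,
        projected_expr=projected_expr,
        seed=seed,
        episode_starts="all",
    )
    value_map, trace, policy = train(
        env, agent_kind=agent_kind, episodes=episodes, seed=seed, **train_kw
    )
    # intensity is non-negative by definition: negative state values carry
    # the off-lattice penalty, not lineage signal, and are clipped before
    # projection so they do not shift the unit normalization
    cell_values = normalize_unit(grid_to_cells(np.maximum(value_map, 0.0), cgmap))
    return IntensityMap(
        node_values=value_map,
        cell_values=cell_values,
        mode=spec.mode,
        spec=spec,
        trace=trace,
        policy=policy,
    )


def lineage_intensity(
    grid: MappedGrid,
    psi: PseudotimeField,
    latent: np.ndarray,
    embedding: Embedding2D,
    cgmap: CellGridMap,
    node_labels: np.ndarray,
    target_clusters,
    start_clusters,
    mode: str = "decision",
    agent_kind: str = "q",
    episodes: int = 1000,
    beta: float = 1.0,
    k_state: int = 15,
    seed: int = 0,
    states: np.ndarray | None = None,
    **train_kw,
) -> IntensityMap:
    """Train an agent with cluster rewards; return the cell intensity map.

    ``target_clusters`` mark the rewarded lineage, ``start_clusters`` the
    episode start region.  ``mode`` selects decision (early) or contribution
    (cumulative) weighting.
    """
    target_clusters = (
        (target_clusters,) if isinstance(target_clusters, str) else tuple(target_clusters)
    )
    start_clusters = (
        (start_clusters,) if isinstance(start_clusters, str) else tuple(start_clusters)
    )
    present = set(np.asarray(node_labels[grid.mapped_nodes], dtype=object).tolist())
    missing = [c for c in target_clusters if c not in present]
    if missing:
        raise ValueError(f"target clusters absent from grid labels: {missing}")
    spec = RewardSpec(
        mode=mode,
        kind="discrete",
        beta=beta,
        start_clusters=start_clusters,
        end_clusters=target_clusters,
    )
    if states is None:
        states = build_states(grid, latent, embedding, k=k_state)
    return _train_intensity(
        grid, psi, states, spec, cgmap, node_labels, None,
        agent_kind, episodes, seed, **train_kw,
    )


def gene_intensity(
    grid: MappedGrid,
    psi: PseudotimeField,
    latent: np.ndarray,
    embedding: Embedding2D,
    cgmap: CellGridMap,
    expression: pd.DataFrame,
    reward_genes,
    punish_genes=(),
    node_labels: np.ndarray | None = None,
    start_clusters=(),
    mode: str = "decision",
    agent_kind: str = "q",
    episodes: int = 1000,
    beta: float = 1.0,
    k_state: int = 15,
    seed: int = 0,
    states: np.ndarray | None = None,
    **train_kw,
) -> IntensityMap:
    """Train an agent with gene-expression rewards (continuous mode).

    ``expression`` is a cells x genes DataFrame; reward/punish gene columns
    are projected onto the grid before training.
    """
    reward_genes = (
        (reward_genes,) if isinstance(reward_genes, str) else tuple(reward_genes)
    )
    punish_genes = (
        (punish_genes,) if isinstance(punish_genes, str) else tuple(punish_genes)
    )
    missing = [g for g in (*reward_genes, *punish_genes)
               if g not in expression.columns]
    if missing:
        raise KeyError(f"genes not found in expression table: {missing}")
    if np.allclose(expression[list(reward_genes)].to_numpy(), 0.0):
        raise ValueError("reward genes have all-zero expression")
    spec = RewardSpec(
        mode=mode,
        kind="continuous",
        beta=beta,
        start_clusters=tuple(start_clusters) if start_clusters else (),
        reward_genes=reward_genes,
        punish_genes=punish_genes,
    )
    cols = list(dict.fromkeys([*reward_genes, *punish_genes]))
    projected = cells_to_grid(expression[cols], cgmap)
    if states is None:
        states = build_states(grid, latent, embedding, k=k_state)
    return _train_intensity(
        grid, psi, states, spec, cgmap, node_labels, projected,
        agent_kind, episodes, seed, **train_kw,
    )


def weighted_pseudotime(intensity: np.ndarray, psi: np.ndarray) -> float:
    """Intensity-weighted mean pseudotime: ``sum(w * psi) / sum(w)``.

    Lower values indicate mass concentrated at more primitive stages.
    """
    w = np.asarray(intensity, dtype=float)
    p = np.asarray(psi, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights are all zero")
    return float((w * p).sum() / total)


def binned_profile(
    values: np.ndarray, psi: np.ndarray, n_bins: int = 50
) -> pd.Series:
    """Mean of ``values`` in equal-width pseudotime bins.

    The pseudotime range is split into ``n_bins`` equal-width bins; the
    series is indexed by bin midpoint, with NaN for empty bins (absence of
    cells, not zero signal).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(values, dtype=float)
    psi = np.asarray(psi, dtype=float)
    lo, hi = np.min(psi), np.max(psi)
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(psi, edges) - 1, 0, n_bins - 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    out = pd.Series(np.nan, index=mids)
    df = pd.DataFrame({"bin": which, "v": values})
    means = df.groupby("bin")["v"].mean()
    out.iloc[means.index] = means.to_numpy()
    return out


def select_branch_markers(
    expr: pd.DataFrame,
    branch_labels: np.ndarray,
    target,
    frac_in: float = 0.25,
    frac_out: float = 0.25,
    top_n: int = 10,
) -> list:
    """Branch marker genes by expression fraction and log-fold change.

    A gene qualifies when expressed (> 0) in at least ``frac_in`` of target
    branch cells and in fewer than ``frac_out`` of the reference (all other)
    cells; qualifying genes are ranked by log2 fold change of mean
    expression and the top ``top_n`` returned.
    """
    branch_labels = np.asarray(branch_labels, dtype=object)
    if branch_labels.shape[0] != expr.shape[0]:
        raise ValueError("branch labels must cover all cells")
    in_mask = branch_labels == target
    if not in_mask.any():
        raise ValueError(f"branch {target!r} has no cells")
    X = expr.to_numpy(dtype=float)
    expressed = X > 0
    f_in = expressed[in_mask].mean(axis=0)
    f_out = expressed[~in_mask].mean(axis=0)
    ok = (f_in >= frac_in) & (f_out < frac_out)
    if not ok.any():
        warnings.warn(f"no gene passes the marker criteria for {target!r}",
                      stacklevel=2)
        return []
    eps = 1e-9
    lfc = np.log2((X[in_mask].mean(axis=0) + eps) / (X[~in_mask].mean(axis=0) + eps))
    cand = np.flatnonzero(ok)
    ranked = cand[np.argsort(-lfc[cand], kind="stable")]
    return [expr.columns[i] for i in ranked[:top_n]]


def rollout_trajectory(
    policy: Policy, env: GridEnv, start_node: int, seed: int = 0
) -> list:
    """Roll the learned policy out from ``start_node`` until termination.

    Returns the visited node sequence (no repeats, length at most
    ``t_max + 1``).
    """
    if not env.grid.mapped[start_node]:
        raise ValueError(f"start node {start_node} is not mapped")
    rng = np.random.default_rng(seed)
    node = env.reset(start_node=start_node)
    path = [node]
    if env.t_max <= 0:
        return path
    while True:
        a = policy.sample(node, rng)
        tr = env.step(a)
        if tr.next_state not in path:  # terminal revisits are not re-recorded
            path.append(tr.next_state)
            node = tr.next_state
        if tr.done:
            break
    return path
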