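# Methods

## Model

`gridfate` treats differentiation on a 2-D embedding as an episodic Markov
decision process over a masked lattice. The pipeline has five stages; the
notation follows the code.

**Grid embedding.** An `n×n` lattice spans the bounding box of the
embedding `X ∈ R^{m×2}` (node coordinates are `n` equally spaced values per
axis, so there are always `n²` nodes). Boundary cells are detected by an
angular sweep: from each *spine point* `s`, every cell gets the guarded
angle `arctan((s_x − X_x + ε)/(s_y − X_y + ε))` with `ε = 1e-6`, rounded to
6 decimals for bucketing; the farthest cell per bucket is a boundary cell.
Masking then ranks, per *observer point*, all lattice nodes and all boundary
cells jointly by distance (ascending, ties broken by insertion index with
nodes before cells); a node whose rank exceeds the maximum boundary-cell
rank plus the margin `j` for any observer is removed. Surviving nodes are
8-connected (Chebyshev lattice distance 1); if the mapped graph is
disconnected, the unmapped nodes on the Bresenham line between the closest
lattice-position pair of the largest and a minor component are re-mapped
until one component remains. The grid boundary is the set of mapped nodes
with fewer than 8 mapped neighbours.

Spine and observer points are not intrinsically defined by the construction;
we use the four axis-extreme cells plus the coordinate-wise centroid for
both — deterministic, parameter-free, and covering all look directions.

**Pseudotime.** Roots are either the mapped node nearest a chosen cell or a
seeded sample of `n_sample` nodes from a root cluster's lattice region
(intersected with the grid boundary by default). All lattice edges carry
unit weight — Dijkstra then equals breadth-first distance; a `√2` diagonal
weighting would be a one-line change but is not the default. The raw field
is the mean over roots of shortest-path distances. If the mapped graph has
several components, the component with the majority of roots (ties: the
larger component, with a warning) is primary; each secondary component is
anchored at its embedding-space closest pair with the main component,
offset by the raw distance already assigned at the main-side node, and
filled by Dijkstra from the anchor. The final field ψ is min–max normalized
to [0, 1]; a constant field normalizes to zeros with a warning.

**Projection.** Continuous values travel between cells and mapped nodes
through k-nearest-neighbour Gaussian kernels (`k = 15`): for a query point,
the bandwidth is the variance of its k neighbour distances, floored at
`1e-12`; weights are normalized Gaussians of squared distance, computed
after subtracting the row-minimum squared distance (a softmax-style
stabilization), so equal distances give exactly uniform weights and a
vanishing bandwidth gives a point mass on the nearest neighbour. Labels move
to nodes by nearest-cell assignment, distance ties resolving to the lowest
cell index. Optional annotation weighting multiplies a cell's projected
value by `log(w_ann)` and therefore requires `w_ann > 1`.

**MDP.** A node's state vector is the mean latent row of its k nearest
cells. Actions are the 8 compass moves R, RT, T, LT, L, LB, B, RB (row along
y, column along x). Rewards:

- *discrete* (lineage): arriving on a node labelled with a target cluster
  pays `exp(−β·ψ') + Δψ` in decision mode or `1 − exp(−β·ψ') + Δψ` in
  contribution mode, where ψ' is the pseudotime of the node reached and
  Δψ the pseudotime progression of the step; other mapped nodes pay 0.
  The progression bonus applies on target arrivals only.
- *continuous* (gene): `w·r̄(s') − (1−w)·p̄(s')` where r̄/p̄ are mean
  projected expression of reward/punish gene sets and `w` is the mode
  weight above. The punish weight is defined as the complementary mode's
  weight — the only weight pair the construction itself defines.

Moving off the mapped region pays −1 and terminates. Episodes also end on
reaching a grid-boundary node outside the start-cluster region, on
revisiting a node of the episode's own trajectory, and after `T_max = 10·n`
steps. `β` defaults to 1.0: unit decay over the normalized pseudotime range.

**Agents.** Tabular Q-learning (zero-initialized `|nodes|×8` table,
ε-greedy with `ε(t) = 0.01 + 0.89·exp(−0.01·t/1000)`); an actor–critic pair
of two-layer perceptrons (hidden width 64, ReLU) whose policy head squashes
logits through `1 + 5·sigmoid` before the softmax — bounding logits to
[1, 6] keeps the policy stochastic — with entropy coefficient 0.01; and a
double DQN (online argmax selects the bootstrap action, the target network
evaluates it; smooth-L1 loss; soft updates with τ = 0.005 by default, or
hard updates every C steps; replay buffer of 10 000 with uniform sampling
once 10% full, batch 64). Networks are plain numpy with manual backprop and
Adam at 1e-3; γ defaults to 0.97 for long lattice traversals. Training is
tracked by a slow EMA (`x̄ ← 0.005·x + 0.995·x̄`) of max-Q or state value
and by trailing 100-episode mean returns; convergence is declared when that
trailing mean moves by less than 1e-3 over 10 consecutive episodes, and an
exhausted episode budget returns the current learner with a warning.

**Intensity and analyses.** The trained critic's node values (max-Q for
value methods, V(s) for actor–critic) are clipped at zero — negative values
carry the off-lattice penalty, not lineage signal — projected onto cells,
and min–max normalized to [0, 1]. Downstream: intensity-weighted mean
pseudotime `Σ(w·ψ)/Σw`; equal-width binned pseudotime profiles (default 50
bins, empty bins reported as missing, not zero — zeros would fabricate
signal at sparse extremes; bin aggregation is the mean); branch-marker
selection (expressed, i.e. > 0, in ≥ 25% of target cells and < 25% of
reference cells, ranked by log2 fold change, top 10); and stochastic policy
rollouts that record each visited node once.

**Metrics.** MAS and PAAC are the mean absolute Pearson correlation of an
intensity vector with the two embedding axes or the first two principal
components; both are implemented directly. ARI, NMI, silhouette,
Calinski–Harabasz and Davies–Bouldin delegate to scikit-learn. The
comprehensive score min–max scales each metric column across methods,
inverts Davies–Bouldin (lower is better), scales constant columns to 0 with
a warning, and averages. The percentile baseline labels cells at or above
the q-th percentile (linear interpolation; threshold ties label 1).

## Defaults

| parameter | default | meaning |
|---|---|---|
| `n` | 50 | lattice resolution per axis (n² nodes) |
| `j` | 3 | masking rank margin |
| `k_neighbors` | 15 | kNN size for projection and state vectors |
| `n_sample` | 10 | root nodes sampled in cluster mode |
| `boundary_only` | true | restrict cluster roots to the grid boundary |
| `β` | 1.0 | pseudotime decay rate of the reward weight (per unit ψ) |
| `γ` | 0.97 | discount factor |
| `T_max` | 10·n | episode truncation (steps) |
| buffer / batch | 10 000 / 64 | replay capacity and minibatch size |

## Episode starts

By default episodes begin uniformly on start-cluster nodes. The intensity
functions instead use exploring starts over all mapped nodes: value
learning needs updates everywhere on the lattice, and under the very slow
exploration decay a random walk from a distal root essentially never
reaches the rewarded region at the problem sizes used here, leaving the
value map empty. The start clusters retain their role in the termination
rule (boundary contact inside the start region does not end an episode).

## Synthetic data

`make_branching_manifold` emulates the geometry a 2-D embedding of a
branching differentiation process provides: a straight trunk occupying the
first 40% of progression, branches fanned over a 120° sector, isotropic
Gaussian positional jitter (default sd 0.05, total extent ≈ 1 — wide enough
that lattice corridors at `n = 50` are several nodes across), one latent
component per branch ramping with progression plus a primitive trunk
component, and one marker gene per branch of the form
`max(0, t − t_branch)` plus noise. Defaults (500 cells, 2 branches, 20
genes) define the package's reference conditions. It does *not* emulate
count statistics (no negative-binomial sampling, no dropout, no library
size), batch structure, or curved/anastomosing topologies; passing tests
therefore demonstrate correctness of the machinery and the qualitative
decision-precedence behaviour on clean branching geometry, not robustness
to real scRNA-seq noise.

`make_toy_gridworld` is a fully mapped lattice MDP with one terminal
rewarded cell and off-lattice moves terminal at −1, bundled with an exact
value-iteration oracle. Note that with all 8 compass actions available the
optimal value at a cell diagonally adjacent to the goal is the full reward
(one diagonal step), not γ·reward.

## Numerical choices

- Variance floor `1e-12` in the Gaussian kernels; the shifted-exponent
  formulation avoids underflow when the bandwidth is tiny.
- `normalize_unit` maps a constant vector to zeros rather than dividing by
  zero; degenerate pseudotime likewise normalizes to zeros with a warning.
- Angle bucketing rounds to 6 decimals; without rounding, float angles are
  almost surely all distinct and the per-bucket argmax is vacuous.
- Mask ranking breaks distance ties by insertion order (stable sort), nodes
  before boundary cells.
- Tabular training is bit-reproducible given seeds; network agents are
  run-reproducible on the same platform.

## Problem sizes

The test suite and `scripts/acceptance.py` use a 500-cell, 2-branch
manifold on a 50×50 lattice with 2 000 tabular-Q episodes per intensity map
(a few seconds per map on one CPU), a 3-branch variant for pseudotime
recovery, and the 5×5 toy gridworld for learner-correctness checks. These
sizes were chosen as the smallest at which the branching geometry is well
resolved by the lattice.

## Limitations

- Everything happens on a 2-D embedding; structure lost by the embedding is
  invisible to the lattice, and shortest-path distance is only a proxy for
  developmental time.
- Root selection is user-supplied; a wrong root propagates through the
  whole pseudotime field.
- No uncertainty quantification on pseudotime or intensity values.
- The multi-component offset rule is a heuristic stitching of disconnected
  islands; relationships between truly separate populations should not be
  over-interpreted.
- The bounded policy logits ([1, 6] pre-softmax) cap how deterministic the
  actor–critic policy can become; greedy behaviour comes from the value
  methods.
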