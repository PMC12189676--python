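# gridfate

Reinforcement-learning analysis of cell fate decisions on 2-D single-cell
embeddings.

Trajectory-inference tools order cells along pseudotime, but they say little
about *where* and *when* fate decisions are made. `gridfate` recasts
differentiation as a sequential decision process: a 2-D embedding (typically
UMAP) is discretized into a masked lattice, every lattice node receives a
shortest-path pseudotime, and the lattice becomes a Markov decision process
whose rewards are tied to a lineage of interest and modulated along
pseudotime. A value-learning agent (tabular Q-learning, actor–critic, or
double DQN) is trained in one of two reward modes, and its state-value
function — projected back onto cells — is the lineage's intensity map:

- **decision mode** — reward weight `exp(-β·ψ)` decays along pseudotime ψ,
  so high values mark early commitment states *before* overt lineage
  contribution;
- **contribution mode** — weight `1 − exp(-β·ψ)` grows along pseudotime, so
  high values mark cumulative lineage output.

The two weights are complementary at every ψ. The package's headline
qualitative property is *decision precedence*: for the same lineage, the
intensity-weighted mean pseudotime `Σ(w·ψ)/Σw` of the decision map is
smaller than that of the contribution map.

It is aimed at computational biologists working on differentiation systems
(hematopoiesis, endocrinogenesis, perturbation atlases) who already have an
embedding, a latent representation and cluster labels, and want quantitative
fate-decision and lineage-contribution scores per cell.

## Method sketch

1. **Grid embedding** — an `n×n` lattice spans the embedding's bounding box.
   Boundary cells are found by an angular sweep from spine points (the
   farthest cell in each angle bucket); lattice nodes ranking beyond the
   data's own boundary from any observer point (margin `j`) are masked.
   Surviving nodes are 8-connected and repaired to a single component.
2. **Pseudotime** — multi-source Dijkstra (unit edge weights) from root
   nodes; disconnected components are anchored at their closest point to the
   main component and offset; the field is min–max normalized to [0, 1].
3. **Projection** — values move between cells and nodes through Gaussian
   kNN kernels (`k=15`) with local-variance bandwidths; labels move by
   nearest-neighbour assignment.
4. **MDP and agents** — states are mean latent vectors of each node's k
   nearest cells; actions are the 8 compass moves; episodes end off-lattice
   (reward −1), on the grid boundary outside the start region, on revisits,
   or after `T_max` steps. Rewards come from target clusters (discrete) or
   projected gene expression (continuous), weighted by mode.
5. **Metrics** — MAS/PAAC (mean absolute Pearson correlation of an
   intensity vector with the two embedding axes / first two PCs), standard
   clustering metrics, and a min–max comprehensive score.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
import numpy as np
import gridfate as gf
from scipy.stats import spearmanr

# a seeded synthetic branching manifold: trunk + two branches, one ramping
# marker gene per branch, ground-truth progression in [0, 1]
m = gf.make_branching_manifold(n_cells=500, n_branches=2, seed=1)
emb = gf.Embedding2D(m.embedding)

grid = gf.build_grid(emb, n=50, j=3)
node_labels = gf.project_labels_to_grid(m.clusters, emb, grid)
starts = gf.select_start(grid, emb, "trunk", labels=m.clusters,
                         node_labels=node_labels, seed=1)
psi = gf.compute_pseudotime(grid, starts)
cgmap = gf.build_cell_grid_map(emb, grid, k=15)
cell_psi = gf.grid_to_cells(psi.psi, cgmap)
print("Spearman(truth, psi) =", round(spearmanr(m.true_time, cell_psi).statistic, 3))

for mode in ("decision", "contribution"):
    im = gf.lineage_intensity(grid, psi, m.latent, emb, cgmap, node_labels,
                              target_clusters="branch_0", start_clusters="trunk",
                              mode=mode, agent_kind="q", episodes=2000, seed=1)
    wpt = gf.weighted_pseudotime(im.cell_values, cell_psi)
    print(f"{mode}: weighted pseudotime = {wpt:.3f}")
```

Output:

```
Spearman(truth, psi) = 0.968
decision: weighted pseudotime = 0.439
contribution: weighted pseudotime = 0.530
```

The lattice pseudotime recovers the ground-truth progression (Spearman
0.968), and the decision map concentrates earlier along pseudotime (0.439)
than the contribution map (0.530) — the decision-precedence property.

The same pipeline is available from the shell:

```bash
gridfate synth --preset y-tree --seed 0 --out fixture.h5ad
gridfate grid --input fixture.h5ad --n 50 --j 3 --out project.h5
gridfate pseudotime --project project.h5 --root-cluster trunk
gridfate run --config config.json --out project.h5
gridfate metrics --project project.h5 --out metrics.csv
```

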