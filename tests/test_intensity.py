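"""Intensity maps and downstream analyses: weighted pseudotime, binned
profiles, marker selection, policy rollout."""

import warnings

import numpy as np
import pandas as pd
import pytest

import gridfate as gf


class TestWeightedPseudotime:
    def test_uniform_weights_give_plain_mean(self):
        psi = np.array([0.1, 0.4, 0.7])
        assert gf.weighted_pseudotime(np.ones(3), psi) == pytest.approx(psi.mean())

    def test_point_mass_returns_that_cell(self):
        w = np.array([0.0, 5.0, 0.0])
        psi = np.array([0.1, 0.4, 0.7])
        assert gf.weighted_pseudotime(w, psi) == pytest.approx(0.4)

    def test_hand_computed_example(self):
        assert gf.weighted_pseudotime(
            np.array([1.0, 0.0, 1.0]), np.array([0.0, 0.5, 1.0])
        ) == pytest.approx(0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gf.weighted_pseudotime(np.zeros(3), np.ones(3))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            gf.weighted_pseudotime(np.array([1.0, -0.1]), np.ones(2))


class TestBinnedProfile:
    def test_constant_values_constant_profile(self):
        psi = np.linspace(0, 1, 200)
        prof = gf.binned_profile(np.full(200, 2.0), psi, n_bins=50)
        np.testing.assert_allclose(prof.dropna().to_numpy(), 2.0)

    def test_identity_values_track_bin_midpoints(self):
        psi = np.linspace(0, 1, 5000)
        prof = gf.binned_profile(psi, psi, n_bins=50)
        mids = prof.index.to_numpy()
        np.testing.assert_allclose(prof.to_numpy(), mids, atol=0.01)

    def test_single_cell_one_bin(self):
        prof = gf.binned_profile(np.array([3.0, 3.0]), np.array([0.5, 0.5]),
                                 n_bins=10)
        assert prof.notna().sum() == 1

    def test_empty_bins_are_missing_not_zero(self):
        psi = np.array([0.0, 0.05, 1.0])
        prof = gf.binned_profile(np.array([1.0, 1.0, 1.0]), psi, n_bins=10)
        assert prof.isna().sum() == 8

    def test_one_bin_returns_global_mean(self):
        vals = np.array([1.0, 2.0, 6.0])
        prof = gf.binned_profile(vals, np.array([0.1, 0.5, 0.9]), n_bins=1)
        assert prof.iloc[0] == pytest.approx(vals.mean())


class TestSelectBranchMarkers:
    @staticmethod
    def _toy():
        # 10 target cells, 10 reference cells, 5 genes with known fractions
        expr = pd.DataFrame(
            {
                "always_on": np.ones(20),               # 100% both: excluded
                "perfect": [1.0] * 10 + [0.0] * 10,     # 100% / 0%: selected
                "low_frac": [1.0] * 2 + [0.0] * 18,     # 20% target: excluded
                "strong": [4.0] * 8 + [0.0] * 12,       # 80% / 0%
                "weak": [0.5] * 8 + [0.0] * 12,         # 80% / 0%, lower lfc
            }
        )
        labels = np.array(["t"] * 10 + ["r"] * 10, dtype=object)
        return expr, labels

    def test_perfect_marker_selected_low_fraction_excluded(self):
        expr, labels = self._toy()
        got = gf.select_branch_markers(expr, labels, "t")
        assert "perfect" in got and "strong" in got
        assert "low_frac" not in got and "always_on" not in got

    def test_ranking_matches_brute_force_log_fold_change(self):
        expr, labels = self._toy()
        got = gf.select_branch_markers(expr, labels, "t", top_n=3)
        # brute-force ranking of the qualifying genes by lfc
        eps = 1e-9
        qual = ["perfect", "strong", "weak"]
        lfc = {
            g: np.log2((expr[g][:10].mean() + eps) / (expr[g][10:].mean() + eps))
            for g in qual
        }
        expected = sorted(qual, key=lambda g: -lfc[g])
        assert got == expected

    def test_no_passing_gene_warns_and_returns_empty(self):
        expr = pd.DataFrame({"g": np.ones(6)})
        labels = np.array(["t"] * 3 + ["r"] * 3, dtype=object)
        with pytest.warns(UserWarning, match="no gene"):
            assert gf.select_branch_markers(expr, labels, "t") == []


@pytest.fixture(scope="module")
def solved_square():
    """A small fully mapped environment with a trained tabular agent."""
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1, size=(300, 2))
    corners = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    emb = gf.Embedding2D(np.vstack([corners, pts]))
    grid = gf.refine_boundary(gf.build_adjacency(gf.make_grid(emb, 7)))
    labels = np.where(emb.coords[:, 0] > 0.8, "goal", "body").astype(object)
    node_labels = gf.project_labels_to_grid(labels, emb, grid)
    psi_vals = grid.lattice_pos[:, 1] / 6.0
    psi = np.where(grid.mapped, psi_vals, np.nan)
    from gridfate.pseudotime import PseudotimeField

    field = PseudotimeField(psi=psi, raw_distance=psi.copy(),
                            component_id=np.where(grid.mapped, 0, -1))
    states = gf.build_states(grid, emb.coords, emb, k=5)
    spec = gf.RewardSpec(mode="contribution", end_clusters=("goal",),
                         start_clusters=("body",))
    env = gf.GridEnv(grid, field, states, spec, node_labels=node_labels,
                     seed=0, episode_starts="all")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value_map, trace, policy = gf.train(env, agent_kind="q", episodes=2000,
                                            seed=0, early_stop=False)
    return dict(env=env, grid=grid, policy=policy, value_map=value_map,
                node_labels=node_labels)


class TestRollout:
    def test_greedy_rollout_reaches_goal_region(self, solved_square):
        s = solved_square
        start = s["grid"].node_id(3, 0)
        path = gf.rollout_trajectory(s["policy"], s["env"], start, seed=0)
        assert s["node_labels"][path[-1]] == "goal"

    def test_no_repeated_nodes_and_length_cap(self, solved_square):
        s = solved_square
        s["env"].t_max = 12
        path = gf.rollout_trajectory(s["policy"], s["env"], s["grid"].node_id(3, 1),
                                     seed=1)
        assert len(path) == len(set(path))
        assert len(path) <= 13
        s["env"].t_max = 10 * s["grid"].n

    def test_tmax_zero_returns_start_only(self, solved_square):
        s = solved_square
        s["env"].t_max = 0
        path = gf.rollout_trajectory(s["policy"], s["env"], s["grid"].node_id(3, 1),
                                     seed=0)
        assert path == [s["grid"].node_id(3, 1)]
        s["env"].t_max = 10 * s["grid"].n

    def test_unmapped_start_rejected(self, solved_square):
        s = solved_square
        s["grid"].mapped[0] = False
        try:
            with pytest.raises(ValueError, match="not mapped"):
                gf.rollout_trajectory(s["policy"], s["env"], 0)
        finally:
            s["grid"].mapped[0] = True


class TestLineageIntensity:
    def test_rewarded_branch_scores_higher(self, ytree_pipeline, ytree_intensities):
        m = ytree_pipeline["manifold"]
        im = ytree_intensities[("branch_0", "contribution")]
        on = im.cell_values[m.clusters == "branch_0"].mean()
        off = im.cell_values[m.clusters == "branch_1"].mean()
        assert on > off

    def test_decision_precedes_contribution(self, ytree_pipeline, ytree_intensities):
        cell_psi = ytree_pipeline["cell_psi"]
        for branch in ("branch_0", "branch_1"):
            dec = gf.weighted_pseudotime(
                ytree_intensities[(branch, "decision")].cell_values, cell_psi
            )
            con = gf.weighted_pseudotime(
                ytree_intensities[(branch, "contribution")].cell_values, cell_psi
            )
            assert dec < con

    def test_cell_values_unit_interval(self, ytree_intensities):
        for im in ytree_intensities.values():
            v = im.cell_values
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_absent_target_cluster_rejected(self, ytree_pipeline):
        p = ytree_pipeline
        with pytest.raises(ValueError, match="absent"):
            gf.lineage_intensity(
                p["grid"], p["psi"], p["manifold"].latent, p["embedding"],
                p["cgmap"], p["node_labels"],
                target_clusters="nonexistent", start_clusters="trunk",
            )

    def test_invariant_to_cell_permutation(self):
        m = gf.make_branching_manifold(n_cells=300, n_branches=2, seed=3)
        perm = np.random.default_rng(0).permutation(m.n_cells)
        results = []
        for order in (np.arange(m.n_cells), perm):
            emb = gf.Embedding2D(m.embedding[order])
            grid = gf.build_grid(emb, n=25, j=3)
            node_labels = gf.project_labels_to_grid(m.clusters[order], emb, grid)
            starts = gf.select_start(grid, emb, "trunk",
                                     labels=m.clusters[order],
                                     node_labels=node_labels, seed=0)
            psi = gf.compute_pseudotime(grid, starts)
            cg = gf.build_cell_grid_map(emb, grid, k=10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                im = gf.lineage_intensity(
                    grid, psi, m.latent[order], emb, cg, node_labels,
                    target_clusters="branch_0", start_clusters="trunk",
                    episodes=500, seed=0, early_stop=False,
                )
            results.append(im.cell_values)
        direct, permuted = results
        np.testing.assert_allclose(permuted, direct[perm], atol=1e-6)


class TestGeneIntensity:
    def test_branch_marker_reward_highlights_branch(self, ytree_pipeline):
        p = ytree_pipeline
        m = p["manifold"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im = gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                m.expression, reward_genes="marker_0",
                node_labels=p["node_labels"], start_clusters="trunk",
                mode="contribution", episodes=1000, seed=0,
                states=p["states"], early_stop=False,
            )
        on = im.cell_values[m.clusters == "branch_0"].mean()
        off = im.cell_values[m.clusters == "branch_1"].mean()
        assert on > off

    def test_decision_peak_precedes_expression_peak(self, ytree_pipeline):
        p = ytree_pipeline
        m = p["manifold"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            im = gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                m.expression, reward_genes="marker_0",
                node_labels=p["node_labels"], start_clusters="trunk",
                mode="decision", episodes=2000, seed=0,
                states=p["states"], early_stop=False,
            )
        cell_psi = p["cell_psi"]
        dec_peak = gf.weighted_pseudotime(im.cell_values, cell_psi)
        expr = np.maximum(m.expression["marker_0"].to_numpy(), 0.0)
        expr_peak = gf.weighted_pseudotime(expr, cell_psi)
        assert dec_peak < expr_peak

    def test_punish_gene_lowers_intensity(self, ytree_pipeline):
        p = ytree_pipeline
        m = p["manifold"]
        common = dict(
            node_labels=p["node_labels"], start_clusters="trunk",
            mode="decision", episodes=800, seed=0, states=p["states"],
            early_stop=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                m.expression, reward_genes="marker_0", **common,
            )
            punished = gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                m.expression, reward_genes="marker_0",
                punish_genes="marker_1", **common,
            )
        # raw (unnormalized) node values drop when punishment is added
        assert np.nansum(punished.node_values) < np.nansum(plain.node_values)

    def test_all_zero_reward_gene_rejected(self, ytree_pipeline):
        p = ytree_pipeline
        m = p["manifold"]
        expr = m.expression.copy()
        expr["dead"] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                expr, reward_genes="dead", node_labels=p["node_labels"],
            )

    def test_unknown_gene_rejected(self, ytree_pipeline):
        p = ytree_pipeline
        m = p["manifold"]
        with pytest.raises(KeyError, match="ghost"):
            gf.gene_intensity(
                p["grid"], p["psi"], m.latent, p["embedding"], p["cgmap"],
                m.expression, reward_genes="ghost",
                node_labels=p["node_labels"],
            )
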