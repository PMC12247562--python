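"""Generators: meshes, parcellations, BOLD, motion traces, panels."""

import numpy as np
import pandas as pd
import pytest

from netgrowth import kcc, dice, fit_lgc, build_lgc_spec, panel_to_arrays
from netgrowth.connectivity import framewise_displacement, flag_high_motion
from netgrowth.surface import make_sphere_mesh
from netgrowth.synthetic import (PanelTruth, make_sphere_parcellation,
                                 perturb_parcellation, simulate_bold,
                                 simulate_motion, simulate_panel)


class TestSurfaceMesh:
    def test_invariants(self, small_mesh):
        small_mesh.validate()  # unit norms, symmetric adjacency, connected

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            make_sphere_mesh(3)


class TestSphereParcellation:
    def test_network_label_set(self, small_mesh):
        parc = make_sphere_parcellation(162, 5, 1, seed=0, mesh=small_mesh)
        assert set(np.unique(parc.network_label)) == {1, 2, 3, 4, 5}

    def test_node_count(self, small_mesh):
        parc = make_sphere_parcellation(162, 5, 2, seed=0, mesh=small_mesh)
        assert set(np.unique(parc.node_label)) == set(range(1, 11))

    def test_deterministic(self, small_mesh):
        a = make_sphere_parcellation(162, 4, 2, seed=3, mesh=small_mesh)
        b = make_sphere_parcellation(162, 4, 2, seed=3, mesh=small_mesh)
        assert np.array_equal(a.network_label, b.network_label)
        assert np.array_equal(a.node_label, b.node_label)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            make_sphere_parcellation(20, 5, 10, seed=0)

    def test_partial_coverage(self, small_mesh):
        parc = make_sphere_parcellation(162, 3, 2, seed=0, mesh=small_mesh,
                                        coverage=0.5)
        frac = (parc.network_label > 0).mean()
        assert 0.4 < frac < 0.6
        parc.validate()

    def test_nodes_contiguous_patches(self, small_parc):
        # every node is connected in the mesh graph
        nb = small_parc.mesh.neighbors
        for node in range(1, small_parc.n_nodes + 1):
            members = set(np.flatnonzero(small_parc.node_label == node))
            seen = {next(iter(members))}
            stack = list(seen)
            while stack:
                v = stack.pop()
                for w in nb[v]:
                    if w in members and w not in seen:
                        seen.add(w)
                        stack.append(w)
            assert seen == members


class TestPerturbParcellation:
    def test_zero_swap_identity(self, small_parc):
        out = perturb_parcellation(small_parc, 0.0, seed=0)
        for k in range(1, small_parc.n_networks + 1):
            assert dice(small_parc.network_label == k,
                        out.network_label == k) == 1.0

    def test_preserves_count_and_universe(self, small_parc):
        out = perturb_parcellation(small_parc, 0.3, seed=5)
        assert out.n_elements == small_parc.n_elements
        assert (set(np.unique(out.network_label))
                == set(np.unique(small_parc.network_label)))
        out.validate()  # node->network invariant survives relabeling

    def test_dsc_decreases_with_swap_fraction(self, small_parc):
        """Expected per-network Dice strictly decreases as the swap fraction
        grows (Monte-Carlo over 20 seeds)."""
        fracs = [0.0, 0.2, 0.5, 1.0]
        means = []
        for frac in fracs:
            vals = []
            for seed in range(20):
                out = perturb_parcellation(small_parc, frac, seed=seed)
                vals.extend(
                    dice(small_parc.network_label == k,
                         out.network_label == k)
                    for k in range(1, small_parc.n_networks + 1))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_full_swap_reaches_chance_level(self, small_parc, rng):
        """At swap fraction 1 the mean Dice matches random relabeling of
        every element (permutation oracle), within 2 Monte-Carlo SDs."""
        n_net = small_parc.n_networks

        def mean_dsc(labels):
            return np.mean([dice(small_parc.network_label == k, labels == k)
                            for k in range(1, n_net + 1)])

        swapped = [mean_dsc(perturb_parcellation(
            small_parc, 1.0, seed=s).network_label) for s in range(20)]
        # chance: uniformly random other network per element
        null = []
        for _ in range(200):
            offs = rng.integers(1, n_net, size=small_parc.n_elements)
            labels = 1 + (small_parc.network_label - 1 + offs) % n_net
            null.append(mean_dsc(labels))
        sd = np.std(null, ddof=1) / np.sqrt(20) + np.std(swapped, ddof=1)
        assert abs(np.mean(swapped) - np.mean(null)) <= 2 * sd + 1e-12

    def test_bad_fraction_raises(self, small_parc):
        with pytest.raises(ValueError):
            perturb_parcellation(small_parc, 1.5, seed=0)


class TestSimulateBold:
    def test_shape(self, small_parc):
        out = simulate_bold(small_parc, 40, seed=0)
        assert out.shape == (small_parc.n_elements, 40)

    def test_zero_noise_gives_identical_member_series(self, small_parc):
        out = simulate_bold(small_parc, 30, within_node_r=0.5, noise_sd=0.0,
                            seed=1)
        members = small_parc.node_label == 1
        assert np.allclose(out[members], out[members][0])
        assert kcc(out[members]) == pytest.approx(1.0)

    def test_zero_coherence_matches_white_noise_null(self, small_parc, rng):
        """With within_node_r = 0 the node KCC sits at the null level of
        independent white-noise series (simulation oracle)."""
        n_t = 60
        out = simulate_bold(small_parc, n_t, within_node_r=0.0, seed=2)
        node_ws = []
        sizes = []
        for node in range(1, small_parc.n_nodes + 1):
            members = small_parc.node_label == node
            node_ws.append(kcc(out[members]))
            sizes.append(members.sum())
        null = []
        for _ in range(300):
            k = int(rng.choice(sizes))
            null.append(kcc(rng.standard_normal((k, n_t))))
        diff = abs(np.mean(node_ws) - np.mean(null))
        sd = (np.std(null, ddof=1) / np.sqrt(300)
              + np.std(node_ws, ddof=1) / np.sqrt(len(node_ws)))
        assert diff < 2 * (sd + np.std(null, ddof=1))

    def test_pairwise_correlation_targets_r(self, small_parc):
        out = simulate_bold(small_parc, 4000, within_node_r=0.5, seed=3)
        rs = []
        for node in range(1, small_parc.n_nodes + 1):
            idx = np.flatnonzero(small_parc.node_label == node)
            c = np.corrcoef(out[idx])
            rs.extend(c[np.triu_indices(idx.size, 1)])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)

    def test_network_level_coherence(self, small_parc):
        out = simulate_bold(small_parc, 4000, within_node_r=0.8,
                            within_network_r=0.4, seed=4)
        node_net = small_parc.network_of_node()
        series = {nd: out[small_parc.node_label == nd].mean(axis=0)
                  for nd in node_net}
        same, diff = [], []
        nodes = sorted(node_net)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                r = np.corrcoef(series[a], series[b])[0, 1]
                (same if node_net[a] == node_net[b] else diff).append(r)
        assert np.mean(same) > 0.25
        assert abs(np.mean(diff)) < 0.1

    @pytest.mark.parametrize("kwargs", [dict(within_node_r=1.0),
                                        dict(within_node_r=-0.1),
                                        dict(within_network_r=1.0),
                                        dict(noise_sd=-1.0)])
    def test_invalid_args(self, small_parc, kwargs):
        with pytest.raises(ValueError):
            simulate_bold(small_parc, 30, seed=0, **kwargs)

    def test_short_series_rejected(self, small_parc):
        with pytest.raises(ValueError):
            simulate_bold(small_parc, 5, seed=0)


class TestSimulateMotion:
    def test_deterministic(self):
        a, _ = simulate_motion(5, 0.2, seed=9)
        b, _ = simulate_motion(5, 0.2, seed=9)
        assert np.array_equal(a, b)

    def test_clean_cohorts_rarely_flagged(self):
        """Clean cohorts produce no 3-MAD mean-FD outliers in >= 95% of
        100 seeds (simulation oracle for the baseline amplitude design)."""
        clean = 0
        for seed in range(100):
            traces, _ = simulate_motion(100, 0.0, seed=seed)
            fd = np.array([framewise_displacement(t).mean() for t in traces])
            clean += not flag_high_motion(fd).any()
        assert clean >= 95

    def test_injected_outliers_always_flagged(self):
        for seed in range(20):
            traces, injected = simulate_motion(50, 0.1, seed=seed)
            fd = np.array([framewise_displacement(t).mean() for t in traces])
            assert flag_high_motion(fd)[injected].all()

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_motion(2, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_motion(5, 1.0, seed=0)


class TestSimulatePanel:
    def test_degenerate_all_fifty(self):
        truth = PanelTruth([50.0, 0.0], np.zeros((2, 2)), 0.0)
        panel = simulate_panel(20, truth, 0.0, seed=0)
        assert np.allclose(panel["rsfc_t"], 50.0)

    def test_no_dropout_complete(self):
        panel = simulate_panel(30, PanelTruth.default(), 0.0, seed=1)
        assert panel["rsfc_t"].notna().all()
        assert len(panel) == 30 * 5

    def test_dropout_monotone(self):
        panel = simulate_panel(200, PanelTruth.default(), 0.3, seed=2)
        wide = panel.pivot(index="subject_id", columns="occasion",
                           values="rsfc_t")
        obs = wide.notna().to_numpy()
        assert (~(~obs[:, :-1] & obs[:, 1:])).all()  # once out, stays out

    def test_covariate_coding(self):
        panel = simulate_panel(500, PanelTruth.default(), 0.0, seed=3)
        subj = panel.drop_duplicates("subject_id")
        assert abs(subj["age0"].mean()) < 1e-9
        assert set(subj["sex"].unique()) <= {0.0, 1.0}
        assert set(subj["education"].unique()) <= {-1.0, 0.0, 1.0}

    def test_moments_match_model(self):
        """Complete-data outcome moments converge to Lambda Psi Lambda' +
        theta I and Lambda alpha (relative error < 5% at n = 5000)."""
        truth = PanelTruth([50.0, 0.4], [[25.0, 2.0], [2.0, 1.0]], 4.0)
        panel = simulate_panel(5000, truth, 0.0, seed=4)
        y = panel.pivot(index="subject_id", columns="occasion",
                        values="rsfc_t").to_numpy()
        lam = truth.loadings()
        mean_implied = lam @ truth.latent_means
        cov_implied = lam @ truth.latent_cov @ lam.T + truth.theta * np.eye(5)
        assert np.allclose(y.mean(axis=0), mean_implied,
                           rtol=0.05, atol=0.3)
        assert np.max(np.abs(np.cov(y.T) - cov_implied)
                      / np.abs(cov_implied)) < 0.05

    def test_parameter_recovery_variant1(self):
        """A simple fixed-effects growth fit recovers the generating slope
        within +-0.1 at n = 2000."""
        truth = PanelTruth([50.0, 0.4], np.zeros((2, 2)), 4.0)
        panel = simulate_panel(2000, truth, 0.1, seed=5)
        fit = fit_lgc(build_lgc_spec(1), panel)
        assert fit.converged
        assert fit.estimates["mean_linear"] == pytest.approx(0.4, abs=0.1)

    def test_nonpsd_cov_rejected(self):
        with pytest.raises(ValueError):
            PanelTruth([50.0, 0.0], [[1.0, 2.0], [2.0, 1.0]], 1.0)

    def test_deterministic(self):
        a = simulate_panel(25, PanelTruth.default(), 0.2, seed=6)
        b = simulate_panel(25, PanelTruth.default(), 0.2, seed=6)
        pd.testing.assert_frame_equal(a, b)
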