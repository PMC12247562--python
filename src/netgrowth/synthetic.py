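"""Synthetic-data generators with known ground truth.

This module produces every input the analysis pipeline consumes:

* spherical parcellations at two granularities (networks and nodes) with
  controllable inter-atlas disagreement,
* BOLD-like element x time series with tunable within-node coherence,
* six-parameter rigid-motion traces with injectable high-motion scans,
* longitudinal panels of within-network connectivity T-scores drawn from a
  latent growth curve model with covariate effects and monotone dropout.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface import SurfaceMesh, make_sphere_mesh

#: Elapsed years of the five measurement occasions (baseline + follow-ups).
DEFAULT_SCHEDULE = np.array([0.0, 1.0, 2.0, 4.0, 7.0])

COVARIATE_NAMES = ("age0", "sex", "education")


@dataclass
class Parcellation:
    """Labeling of mesh vertices (or grid voxels) into networks and nodes.

    ``network_label`` and ``node_label`` are per-element integers; 0 means
    unassigned.  Every nonzero node belongs to exactly one network, and the
    nonzero label sets are contiguous from 1.
    """

    network_label: np.ndarray
    node_label: np.ndarray
    mesh: SurfaceMesh | None = None

    @property
    def n_elements(self) -> int:
        return self.network_label.size

    @property
    def n_networks(self) -> int:
        return int(self.network_label.max(initial=0))

    @property
    def n_nodes(self) -> int:
        return int(self.node_label.max(initial=0))

    def network_of_node(self) -> dict[int, int]:
        """Map node id -> network id; raises if a node straddles networks."""
        out: dict[int, int] = {}
        for node in np.unique(self.node_label):
            if node == 0:
                continue
            nets = np.unique(self.network_label[self.node_label == node])
            if nets.size != 1:
                raise ValueError(f"node {node} maps to networks {nets}")
            out[int(node)] = int(nets[0])
        return out

    def validate(self) -> None:
        if self.network_label.shape != self.node_label.shape:
            raise ValueError("network and node labels must share a shape")
        for arr, what in ((self.network_label, "network"),
                          (self.node_label, "node")):
            labels = np.unique(arr[arr > 0])
            if labels.size and not np.array_equal(
                    labels, np.arange(1, labels.size + 1)):
                raise ValueError(f"{what} labels must be contiguous from 1")
        self.network_of_node()

    def network_masks(self) -> dict[int, np.ndarray]:
        return {k: self.network_label == k
                for k in range(1, self.n_networks + 1)}


def _multi_source_bfs(neighbors: list, seeds: np.ndarray,
                      labels_of_seeds: np.ndarray,
                      eligible: np.ndarray | None = None,
                      max_assigned: int | None = None) -> np.ndarray:
    """Grow contiguous patches from seed vertices; each vertex takes the label
    of the first seed patch to reach it (breadth-first, so roughly the nearest
    seed in graph distance).  Growth stops once ``max_assigned`` vertices are
    labeled, leaving the rest unassigned (label 0)."""
    n = len(neighbors)
    out = np.zeros(n, dtype=np.int32)
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    frontier = list(seeds)
    out[seeds] = labels_of_seeds
    assigned = len(frontier)
    while frontier:
        nxt = []
        for v in frontier:
            lab = out[v]
            for w in neighbors[v]:
                if eligible[w] and out[w] == 0:
                    if max_assigned is not None and assigned >= max_assigned:
                        return out
                    out[w] = lab
                    assigned += 1
                    nxt.append(w)
        frontier = nxt
    return out


def make_sphere_parcellation(n_vertices: int, n_networks: int,
                             nodes_per_network: int, seed: int,
                             mesh: SurfaceMesh | None = None,
                             coverage: float = 1.0) -> Parcellation:
    """Generate a spherical parcellation by region growing.

    Networks are grown breadth-first from ``n_networks`` random seed vertices;
    nodes are then grown the same way inside each network, which yields
    contiguous, roughly equal-sized parcels like real atlases.  ``coverage``
    is the fraction of vertices that get assigned at all; real network
    atlases leave part of the surface unlabeled (omitted structures), which
    is what gives the spin test its contrast between an atlas and its
    rotated copies.
    """
    if n_networks < 1 or nodes_per_network < 1:
        raise ValueError("need at least one network and one node per network")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if int(coverage * n_vertices) < n_networks * nodes_per_network:
        raise ValueError(
            f"{n_vertices} vertices at coverage {coverage} cannot host "
            f"{n_networks}x{nodes_per_network} nodes")
    if mesh is None:
        mesh = make_sphere_mesh(n_vertices)
    elif mesh.n_vertices != n_vertices:
        raise ValueError("mesh size does not match n_vertices")
    rng = np.random.default_rng(seed)

    net_seeds = rng.choice(n_vertices, size=n_networks, replace=False)
    cap = None if coverage == 1.0 else int(round(coverage * n_vertices))
    network = _multi_source_bfs(mesh.neighbors, net_seeds,
                                np.arange(1, n_networks + 1),
                                max_assigned=cap)

    node = np.zeros(n_vertices, dtype=np.int32)
    next_label = 1
    for k in range(1, n_networks + 1):
        members = np.flatnonzero(network == k)
        if members.size < nodes_per_network:
            raise ValueError(
                f"network {k} has only {members.size} vertices for "
                f"{nodes_per_network} nodes; use a larger mesh")
        seeds = rng.choice(members, size=nodes_per_network, replace=False)
        local = _multi_source_bfs(
            mesh.neighbors, seeds,
            np.arange(next_label, next_label + nodes_per_network),
            eligible=(network == k))
        node[members] = local[members]
        next_label += nodes_per_network

    parc = Parcellation(network_label=network, node_label=node, mesh=mesh)
    parc.validate()
    return parc


def perturb_parcellation(parc: Parcellation, swap_fraction: float,
                         seed: int) -> Parcellation:
    """Reassign ~``swap_fraction`` of elements to a random other network.

    A swapped element's node label becomes the nearest node (by centroid
    distance) among the nodes of its new network, so the node->network
    invariant is preserved.  Creates atlas pairs with controllable Dice
    overlap, emulating inter-atlas disagreement.
    """
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError("swap_fraction must be in [0, 1]")
    if parc.n_networks < 2:
        raise ValueError("need >=2 networks to swap between")
    rng = np.random.default_rng(seed)
    assigned = np.flatnonzero(parc.network_label > 0)
    n_swap = int(round(swap_fraction * assigned.size))
    network = parc.network_label.copy()
    node = parc.node_label.copy()
    if n_swap == 0:
        return Parcellation(network, node, parc.mesh)

    if parc.mesh is not None:
        coords = parc.mesh.coordinates
    else:  # fall back to index positions for grid-less label arrays
        coords = np.arange(n, dtype=float)[:, None]
    node_to_net = parc.network_of_node()
    centroids = {nd: coords[parc.node_label == nd].mean(axis=0)
                 for nd in node_to_net}
    nodes_by_net: dict[int, list[int]] = {}
    for nd, net in node_to_net.items():
        nodes_by_net.setdefault(net, []).append(nd)

    swap_idx = rng.choice(assigned, size=n_swap, replace=False)
    offsets = rng.integers(1, parc.n_networks, size=n_swap)
    for idx, off in zip(swap_idx, offsets):
        old = parc.network_label[idx]
        new = 1 + (old - 1 + off) % parc.n_networks
        network[idx] = new
        cands = nodes_by_net[new]
        d = [np.linalg.norm(coords[idx] - centroids[c]) for c in cands]
        node[idx] = cands[int(np.argmin(d))]
    return Parcellation(network, node, parc.mesh)


def simulate_bold(parc: Parcellation, n_timepoints: int,
                  within_node_r: float = 0.5,
                  within_network_r: float = 0.0,
                  noise_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Element x time BOLD-like series with tunable coherence structure.

    Signal model: each network carries a latent standard-normal series
    g_m(t); node k of network m has

        z_k(t) = sqrt(s) * g_m(t) + sqrt(1 - s) * u_k(t),  s = within_network_r

    and element e of node k observes

        x_e(t) = sqrt(r) * z_k(t) + sqrt(1 - r) * noise_sd * xi_e(t)

    with independent unit-normal u_k and xi_e.  At the default ``noise_sd=1``
    the expected pairwise correlation of two elements of one node is exactly
    ``within_node_r``; two nodes of one network correlate at
    ``within_network_r`` while nodes of different networks are independent
    (the structure a node-to-network silhouette responds to).  ``noise_sd=0``
    makes member series identical.  Unassigned elements carry pure noise.
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    if not 0.0 <= within_node_r < 1.0:
        raise ValueError("within_node_r must be in [0, 1)")
    if not 0.0 <= within_network_r < 1.0:
        raise ValueError("within_network_r must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    net_latent = rng.standard_normal((parc.n_networks + 1, n_timepoints))
    node_noise = rng.standard_normal((parc.n_nodes + 1, n_timepoints))
    noise = rng.standard_normal((parc.n_elements, n_timepoints))
    node_net = np.zeros(parc.n_nodes + 1, dtype=int)
    for nd, net in parc.network_of_node().items():
        node_net[nd] = net
    s = within_network_r
    latent = (np.sqrt(s) * net_latent[node_net]
              + np.sqrt(1.0 - s) * node_noise)
    latent[0] = 0.0  # unassigned elements get pure noise
    r = within_node_r
    return (np.sqrt(r) * latent[parc.node_label]
            + np.sqrt(1.0 - r) * noise_sd * noise)


def simulate_motion(n_scans: int, outlier_fraction: float = 0.0,
                    seed: int = 0, n_frames: int = 100,
                    base_translation_mm: float = 0.05,
                    base_rotation_rad: float = 5e-4,
                    outlier_scale: float = 10.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Six-parameter rigid-motion traces with injectable high-motion scans.

    Baseline scans follow a smooth AR(1) drift whose per-scan amplitude is
    drawn uniformly in +/-40% of the base amplitude.  The bounded amplitude
    distribution keeps every clean scan's mean FD well inside the
    median + 3*MAD envelope (a Gaussian-tailed amplitude would flag ~2% of
    clean scans), so flagged scans genuinely reflect injected outliers,
    whose amplitude is inflated by ``outlier_scale``.

    Returns
    -------
    traces : (n_scans, n_frames, 6) array
        Translations (mm) in columns 0-2, rotations (radians) in 3-5.
    is_outlier : (n_scans,) bool array
        Ground-truth injected-outlier indicator.
    """
    if n_scans < 3:
        raise ValueError("need at least 3 scans")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_out = int(round(outlier_fraction * n_scans))
    is_outlier = np.zeros(n_scans, dtype=bool)
    if n_out:
        is_outlier[rng.choice(n_scans, size=n_out, replace=False)] = True

    amp = np.concatenate([np.full(3, base_translation_mm),
                          np.full(3, base_rotation_rad)])
    phi = 0.9
    innov = rng.standard_normal((n_scans, n_frames, 6))
    traces = np.empty_like(innov)
    traces[:, 0] = innov[:, 0]
    for t in range(1, n_frames):
        traces[:, t] = phi * traces[:, t - 1] + np.sqrt(1 - phi**2) * innov[:, t]
    scan_amp = rng.uniform(0.6, 1.4, size=n_scans)
    scan_amp[is_outlier] *= outlier_scale
    traces *= scan_amp[:, None, None] * amp[None, None, :]
    return traces, is_outlier


@dataclass
class PanelTruth:
    """Generative latent-growth truth for a longitudinal connectivity panel.

    ``latent_means`` has one entry per growth factor (intercept, linear slope
    and, if present, quadratic slope), in T-score units.  ``covariate_effects``
    is a (factors x 3) matrix of regressions of (age0, sex, education) on the
    factors.  Residual variance ``theta`` is constant over occasions.
    """

    latent_means: np.ndarray
    latent_cov: np.ndarray
    theta: float
    covariate_effects: np.ndarray | None = None
    loadings_schedule: np.ndarray = field(
        default_factory=lambda: DEFAULT_SCHEDULE.copy())

    def __post_init__(self):
        self.latent_means = np.asarray(self.latent_means, dtype=float)
        self.latent_cov = np.asarray(self.latent_cov, dtype=float)
        self.loadings_schedule = np.asarray(self.loadings_schedule, float)
        q = self.latent_means.size
        if self.latent_cov.shape != (q, q):
            raise ValueError("latent_cov shape must match latent_means")
        if not np.allclose(self.latent_cov, self.latent_cov.T):
            raise ValueError("latent_cov must be symmetric")
        eig = np.linalg.eigvalsh(self.latent_cov)
        if eig.min() < -1e-10:
            raise ValueError("latent_cov must be positive semidefinite")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if self.covariate_effects is None:
            self.covariate_effects = np.zeros((q, 3))
        else:
            self.covariate_effects = np.asarray(self.covariate_effects, float)
            if self.covariate_effects.shape != (q, 3):
                raise ValueError("covariate_effects must be (factors, 3)")

    @property
    def n_factors(self) -> int:
        return self.latent_means.size

    def loadings(self) -> np.ndarray:
        """Occasions x factors loading matrix: 1, t, t^2 columns."""
        t = self.loadings_schedule
        cols = [np.ones_like(t), t, t**2][: self.n_factors]
        return np.column_stack(cols)

    @classmethod
    def default(cls) -> "PanelTruth":
        """Linear growth with intercept/slope variance and covariate effects.

        Intercept mean 50 (T-score metric at baseline), small positive slope,
        intercept variance 25, slope variance 1, residual variance 4; a
        negative age effect on baseline connectivity of roughly the pooled
        size observed in aging cohorts.
        """
        return cls(
            latent_means=np.array([50.0, 0.4]),
            latent_cov=np.array([[25.0, 0.0], [0.0, 1.0]]),
            theta=4.0,
            covariate_effects=np.array([[-0.28, 1.0, 1.5],
                                        [-0.01, 0.0, 0.0]]),
        )


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Time-invariant covariates: mean-centered baseline age (years), sex
    (0 = female, 1 = male, roughly balanced) and 3-level education coded
    {-1, 0, 1} with 0 = medium level."""
    age0 = rng.normal(0.0, 5.0, size=n)
    age0 -= age0.mean()
    sex = (rng.random(n) < 0.513).astype(float)
    education = rng.choice([-1.0, 0.0, 1.0], size=n, p=[0.25, 0.5, 0.25])
    return pd.DataFrame({"age0": age0, "sex": sex, "education": education})


def simulate_panel(n_subjects: int, truth: PanelTruth | None = None,
                   dropout_per_wave: float = 0.15, seed: int = 0,
                   atlas: str = "synthetic", network: str = "NET",
                   age_dependent_dropout: bool = False) -> pd.DataFrame:
    """Longitudinal connectivity panel from a latent growth curve truth.

    Outcomes follow y_it = Lambda_t . eta_i + eps_it with
    eta_i ~ N(latent_means + covariate_effects . x_i, latent_cov) and
    eps ~ N(0, theta).  Dropout is monotone (once missing, missing at every
    later occasion); by default the per-wave dropout probability is the same
    for everyone (MAR by design).  With ``age_dependent_dropout`` the per-wave
    probability increases with observed baseline age, a stress test for
    estimators that assume missing-at-random.

    Returns a tidy frame with one row per subject x occasion (missing
    outcomes are NaN): subject_id, occasion, elapsed_years, atlas, network,
    rsfc_t, age0, sex, education.
    """
    if truth is None:
        truth = PanelTruth.default()
    if not 0.0 <= dropout_per_wave < 1.0:
        raise ValueError("dropout_per_wave must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(n_subjects, rng)
    X = cov.to_numpy()
    lam = truth.loadings()
    q = truth.n_factors
    n_occ = lam.shape[0]

    eta_mean = truth.latent_means[None, :] + X @ truth.covariate_effects.T
    chol = np.linalg.cholesky(
        truth.latent_cov + 1e-12 * np.eye(q)) if truth.latent_cov.any() \
        else np.zeros((q, q))
    eta = eta_mean + rng.standard_normal((n_subjects, q)) @ chol.T
    eps = rng.standard_normal((n_subjects, n_occ)) * np.sqrt(truth.theta)
    y = eta @ lam.T + eps

    # monotone dropout: subject drops before wave t with prob dropout_per_wave
    observed = np.ones((n_subjects, n_occ), dtype=bool)
    if dropout_per_wave > 0:
        if age_dependent_dropout:
            # logistic shift: older subjects drop out more often
            z = cov["age0"].to_numpy() / 5.0
            p = 1.0 / (1.0 + np.exp(-(np.log(dropout_per_wave /
                                            (1 - dropout_per_wave)) + 0.5 * z)))
        else:
            p = np.full(n_subjects, dropout_per_wave)
        for t in range(1, n_occ):
            drop_now = rng.random(n_subjects) < p
            observed[:, t] = observed[:, t - 1] & ~drop_now
    y = np.where(observed, y, np.nan)

    rows = []
    for i in range(n_subjects):
        for t in range(n_occ):
            rows.append((i, t, truth.loadings_schedule[t], atlas, network,
                         y[i, t], X[i, 0], X[i, 1], X[i, 2]))
    return pd.DataFrame(rows, columns=[
        "subject_id", "occasion", "elapsed_years", "atlas", "network",
        "rsfc_t", "age0", "sex", "education"])
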