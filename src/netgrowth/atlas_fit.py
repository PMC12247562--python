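"""How well does a parcellation fit the data?

Three complementary diagnostics:

* **Regional homogeneity (ReHo)** — Kendall's coefficient of concordance
  (KCC, W) of each element's time series with its neighbors; a good node
  definition groups elements with coherent BOLD fluctuations.
* **Silhouette coefficient (SICO)** of the node-to-network allocation,
  computed on connectivity dissimilarity 1 - r; negative values suggest a
  node sits better in another network.
* **Spin test** — a spatial null model: the spherical parcellation is
  randomly rotated so parcel shapes and sizes survive but their alignment
  with the data does not; the empirical metric is compared against the
  rotated-atlas distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .overlap import bonferroni_adjust, rank_sum_test


# --------------------------------------------------------------------------
# Kendall's W / ReHo
# --------------------------------------------------------------------------

def kcc(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series over n points.

    Each series is ranked over time (midranks for ties); R_i is the rank sum
    at timepoint i and

        W = (sum R_i^2 - n Rbar^2) / ((1/12) K^2 (n^3 - n)),

    with Rbar = K (n + 1) / 2.  W is 1 for K identical (non-constant)
    series and near 0 for independent ones.  No tie-correction term is
    applied beyond midranking.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2 or series.shape[1] < 2:
        raise ValueError("series must be (K >= 2, n >= 2)")
    if (series.std(axis=1) == 0).any():
        warnings.warn("constant series: using midranks, W may be deflated")
    ranks = stats.rankdata(series, axis=1)
    return _kcc_from_ranks(ranks)


def _kcc_from_ranks(ranks: np.ndarray) -> float:
    k, n = ranks.shape
    r_i = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    num = float(np.sum(r_i**2) - n * rbar**2)
    den = (k**2 * (n**3 - n)) / 12.0
    return num / den


@dataclass
class RehoResult:
    """Per-element W with node and network summaries."""

    element_w: np.ndarray          # NaN where undefined (isolated element)
    k_used: np.ndarray             # neighborhood size per element
    node_mean: dict = field(default_factory=dict)
    network_mean: dict = field(default_factory=dict)


def reho_map(element_series: np.ndarray, neighbors: list,
             parc=None) -> RehoResult:
    """KCC of every element with its neighborhood.

    ``neighbors`` is a per-element list of neighbor indices (mesh adjacency
    for surfaces, 26-connectivity for volume grids via
    :func:`grid_neighbors`).  An element's neighborhood is itself plus its
    available neighbors, with K set to the actual neighborhood size, so
    boundary elements are handled without padding.  Isolated elements get
    NaN.  If ``parc`` is given, per-node means and unweighted per-network
    means (over member node means) are attached.
    """
    series = np.asarray(element_series, dtype=float)
    n_el, n_t = series.shape
    if len(neighbors) != n_el:
        raise ValueError("neighbor list must match the element count")
    ranks = stats.rankdata(series, axis=1)
    w = np.full(n_el, np.nan)
    k_used = np.zeros(n_el, dtype=int)
    for e in range(n_el):
        nb = neighbors[e]
        if len(nb) == 0:
            continue
        members = np.concatenate([[e], nb])
        k_used[e] = members.size
        w[e] = _kcc_from_ranks(ranks[members])
    result = RehoResult(element_w=w, k_used=k_used)
    if parc is not None:
        node_to_net = parc.network_of_node()
        for node, net in node_to_net.items():
            vals = w[parc.node_label == node]
            result.node_mean[node] = float(np.nanmean(vals))
        for net in range(1, parc.n_networks + 1):
            node_means = [result.node_mean[nd]
                          for nd, nn in node_to_net.items() if nn == net]
            if node_means:
                result.network_mean[net] = float(np.mean(node_means))
    return result


def grid_neighbors(shape: tuple) -> list:
    """26-connectivity neighbor lists for a 3D voxel grid."""
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz).reshape(shape)
    out = []
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                nb = []
                for dx, dy, dz in offs:
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        nb.append(idx[xx, yy, zz])
                out.append(np.array(nb, dtype=np.intp))
    return out


# --------------------------------------------------------------------------
# silhouette of node-to-network allocation
# --------------------------------------------------------------------------

@dataclass
class SicoResult:
    node_a: dict
    node_b: dict
    node_sico: dict
    closest_network: dict
    network_mean: dict
    excluded_nodes: list


def silhouette_nodes(node_corr: np.ndarray, assignment: dict) -> SicoResult:
    """Silhouette coefficient of each node's network allocation.

    Dissimilarity between nodes i, j is 1 - r(v_i, v_j).  a_i is the mean
    dissimilarity to same-network nodes (divisor n_k - 1); b_i is the mean
    dissimilarity to the nodes of the closest other network (the network
    minimizing that mean); SICO_i = (b_i - a_i) / max(a_i, b_i).  Nodes of
    singleton networks have undefined a_i and are excluded with a warning.
    """
    corr = np.asarray(node_corr, dtype=float)
    nodes = sorted(assignment)
    pos = {nd: i for i, nd in enumerate(nodes)}
    if corr.shape != (len(nodes), len(nodes)):
        raise ValueError("node_corr must be square over the assigned nodes")
    networks = sorted(set(assignment.values()))
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    members = {net: [nd for nd in nodes if assignment[nd] == net]
               for net in networks}
    dis = 1.0 - corr

    node_a, node_b, node_s, closest = {}, {}, {}, {}
    excluded = []
    for nd in nodes:
        net = assignment[nd]
        same = [pos[m] for m in members[net] if m != nd]
        if not same:
            excluded.append(nd)
            continue
        a_i = float(np.mean(dis[pos[nd], same]))
        best_net, b_i = None, np.inf
        for other in networks:
            if other == net:
                continue
            d = float(np.mean(dis[pos[nd], [pos[m] for m in members[other]]]))
            if d < b_i:
                best_net, b_i = other, d
        denom = max(a_i, b_i)
        node_a[nd], node_b[nd] = a_i, b_i
        closest[nd] = best_net
        node_s[nd] = 0.0 if denom == 0 else (b_i - a_i) / denom
    if excluded:
        warnings.warn(f"nodes of singleton networks excluded: {excluded}")
    network_mean = {
        net: float(np.mean([node_s[nd] for nd in members[net]
                            if nd in node_s]))
        for net in networks if any(nd in node_s for nd in members[net])}
    return SicoResult(node_a=node_a, node_b=node_b, node_sico=node_s,
                      closest_network=closest, network_mean=network_mean,
                      excluded_nodes=excluded)


# --------------------------------------------------------------------------
# spin test
# --------------------------------------------------------------------------

def apply_rotation(parc, rotation: Rotation) -> tuple:
    """Relabel a spherical parcellation under one rotation.

    The rotation is applied to the vertex cloud and every vertex takes the
    labels of its nearest rotated vertex.  Returns
    ``(network_label, node_label)`` arrays; the identity rotation returns
    the labels unchanged.
    """
    if parc.mesh is None:
        raise ValueError("rotation needs a parcellation on a spherical mesh")
    coords = parc.mesh.coordinates
    if not np.allclose(np.linalg.norm(coords, axis=1), 1.0, atol=1e-6):
        raise ValueError("mesh coordinates are not spherical")
    rotated = rotation.apply(coords)
    _, nearest = cKDTree(rotated).query(coords, k=1)
    return parc.network_label[nearest], parc.node_label[nearest]


def spin_rotate(parc, n_rotations: int, seed: int) -> list:
    """Randomly rotated copies of a spherical parcellation.

    Each rotation applies a uniform random 3D rotation to the vertex cloud;
    every vertex then takes the labels of the nearest rotated vertex, so
    parcel shapes and sizes are approximately preserved while their
    alignment with the data is destroyed.  Deterministic per seed.

    Returns a list of (network_label, node_label) arrays.
    """
    rng = np.random.default_rng(seed)
    rotations = Rotation.random(n_rotations, rng=rng)
    return [apply_rotation(parc, rot) for rot in rotations]


def spin_pvalue(empirical: float, nulls, tail: str = "greater") -> float:
    """Spin-test p-value with the add-one rule (never exactly zero).

    p = (1 + #{null >= empirical}) / (1 + n_rotations) for the 'greater'
    tail (is the empirical metric larger than under spatially structured
    chance?).
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    if tail == "greater":
        exceed = np.sum(nulls >= empirical)
    elif tail == "less":
        exceed = np.sum(nulls <= empirical)
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    return float((1 + exceed) / (1 + nulls.size))


@dataclass
class SpinNulls:
    n_rotations: int
    nulls: np.ndarray
    empirical: float
    p_value: float
    seed: int


def _network_mean_reho(w: np.ndarray, network_label: np.ndarray,
                       node_label: np.ndarray) -> dict:
    """Unweighted network means of node-mean W for given label arrays."""
    out = {}
    for net in np.unique(network_label[network_label > 0]):
        node_means = []
        for nd in np.unique(node_label[network_label == net]):
            if nd == 0:
                continue
            sel = (node_label == nd) & (network_label == net)
            vals = w[sel]
            if np.isfinite(vals).any():
                node_means.append(np.nanmean(vals))
        if node_means:
            out[int(net)] = float(np.mean(node_means))
    return out


def spin_test_reho(element_w: np.ndarray, parc, n_rotations: int = 100,
                   seed: int = 0) -> SpinNulls:
    """Spin test on the across-network mean of network-mean ReHo.

    The empirical value averages the per-network means (node means first,
    unweighted) under the actual parcellation; each null does the same
    under a rotated parcellation.
    """
    emp = float(np.mean(list(_network_mean_reho(
        element_w, parc.network_label, parc.node_label).values())))
    nulls = []
    for net_lab, node_lab in spin_rotate(parc, n_rotations, seed):
        nm = _network_mean_reho(element_w, net_lab, node_lab)
        nulls.append(float(np.mean(list(nm.values()))))
    nulls = np.asarray(nulls)
    return SpinNulls(n_rotations=n_rotations, nulls=nulls, empirical=emp,
                     p_value=spin_pvalue(emp, nulls), seed=seed)


def spin_test_sico(element_series: np.ndarray, parc,
                   n_rotations: int = 100, seed: int = 0) -> SpinNulls:
    """Spin test on the across-network mean silhouette coefficient.

    Node series are element averages; for every rotated atlas the node
    connectivity and allocation silhouette are recomputed from scratch.
    """

    def _mean_sico(net_lab, node_lab):
        assignment = {}
        series = []
        for nd in np.unique(node_lab[node_lab > 0]):
            sel = node_lab == nd
            nets, counts = np.unique(net_lab[sel & (net_lab > 0)],
                                     return_counts=True)
            if nets.size == 0:
                continue
            assignment[int(nd)] = int(nets[np.argmax(counts)])
            series.append(element_series[sel].mean(axis=0))
        if len(assignment) < 3 or len(set(assignment.values())) < 2:
            return np.nan
        corr = np.corrcoef(np.vstack(series))
        res = silhouette_nodes(corr, assignment)
        return float(np.mean(list(res.network_mean.values())))

    emp = _mean_sico(parc.network_label, parc.node_label)
    nulls = np.array([_mean_sico(nl, dl) for nl, dl in
                      spin_rotate(parc, n_rotations, seed)])
    nulls = nulls[np.isfinite(nulls)]
    return SpinNulls(n_rotations=n_rotations, nulls=nulls, empirical=emp,
                     p_value=spin_pvalue(emp, nulls), seed=seed)


# --------------------------------------------------------------------------
# cross-atlas comparisons of fit metrics
# --------------------------------------------------------------------------

def spearman(x, y) -> tuple:
    """Spearman rank correlation with midrank ties (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_atlas_metrics(metrics: pd.DataFrame, ages=None) -> dict:
    """Pairwise atlas comparisons and age correlations of a fit metric.

    ``metrics`` is a subjects x atlases frame of per-subject metric values
    (one network, or the across-network mean).  All pairwise rank-sum tests
    form one Bonferroni family; the age correlations form another.
    """
    atlases = list(metrics.columns)
    if len(atlases) < 2:
        raise ValueError("need at least two atlases")
    pairs = list(itertools.combinations(atlases, 2))
    rows = []
    for a, b in pairs:
        w, p = rank_sum_test(metrics[a].dropna(), metrics[b].dropna())
        rows.append({"atlas_a": a, "atlas_b": b, "W": w, "p": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = bonferroni_adjust(pairwise["p"], len(pairs))

    correlations = None
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        rows = []
        for a in atlases:
            rho, p = spearman(metrics[a].to_numpy(), ages)
            rows.append({"atlas": a, "rho": rho, "p": p})
        correlations = pd.DataFrame(rows)
        correlations["p_adj"] = bonferroni_adjust(correlations["p"],
                                                  len(atlases))
    return {"pairwise": pairwise, "age_correlations": correlations}
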