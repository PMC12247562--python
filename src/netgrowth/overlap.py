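"""Spatial overlap of network definitions and group comparisons on it.

The Dice similarity coefficient (DSC) 2|A&B| / (|A|+|B|) quantifies how much
two atlases agree on where a named network lives.  Overlap values are
tabulated over all unordered atlas-variant pairs per network, grouped into
intra- vs inter-atlas pairs and primary vs higher-order networks, and
compared with Kruskal-Wallis and rank-sum tests under Bonferroni correction.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical network taxonomy: primary processing vs higher-order networks.
NETWORK_CLASS = {
    "ON": "primary", "PN": "primary",
    "M-FPN": "higher-order", "L-FPN": "higher-order",
    "M-CIN": "higher-order",
}


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on one grid.

    2 |A & B| / (|A| + |B|); 1 for identical nonempty masks, 0 for disjoint
    ones.  Undefined (error) when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("masks must be defined on the same element grid")
    size = a.sum() + b.sum()
    if size == 0:
        raise ValueError("Dice coefficient undefined: both masks empty")
    return 2.0 * np.logical_and(a, b).sum() / size


def network_node_partition(network_masks: dict, node_label: np.ndarray
                           ) -> dict:
    """Intersect a node parcellation with binary network masks.

    Each output node is the intersection of an input node with one network
    mask; a node straddling k networks yields k restricted nodes and empty
    intersections are dropped.  Returns
    ``{network: {node_id: boolean mask}}``.
    """
    node_label = np.asarray(node_label)
    out: dict = {}
    for net, mask in network_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != node_label.shape:
            raise ValueError("network mask grid does not match node labels")
        restricted = {}
        for node in np.unique(node_label[(node_label > 0) & mask]):
            restricted[int(node)] = (node_label == node) & mask
        out[net] = restricted
    return out


def assign_nodes_by_max_dice(node_label: np.ndarray, network_masks: dict
                             ) -> tuple[dict, list]:
    """Assign each node to the network with the highest Dice coefficient.

    Ties are broken toward the network whose key sorts first (for integer
    labels: the lowest label).  Nodes with zero Dice to every network are
    returned separately as unassigned.
    """
    node_label = np.asarray(node_label)
    mapping: dict = {}
    unassigned: list = []
    nets = sorted(network_masks)
    for node in np.unique(node_label[node_label > 0]):
        node_mask = node_label == node
        best_net, best_dsc = None, 0.0
        for net in nets:
            d = dice(node_mask, network_masks[net])
            if d > best_dsc:
                best_net, best_dsc = net, d
        if best_net is None:
            unassigned.append(int(node))
        else:
            mapping[int(node)] = best_net
    return mapping, unassigned


def build_dsc_table(variants: dict, network_names: dict,
                    atlas_family_of_variant: dict,
                    network_class: dict | None = None) -> pd.DataFrame:
    """Dice table over all unordered variant pairs and all networks.

    Parameters
    ----------
    variants : dict of variant name -> per-element network label array
        (a :class:`~netgrowth.synthetic.Parcellation` is accepted too).
    network_names : dict of network label (int) -> network name.
    atlas_family_of_variant : dict of variant name -> atlas family; a pair is
        ``intra-atlas`` when both variants share a family, else
        ``inter-atlas``.
    network_class : optional dict of network name -> 'primary'/'higher-order';
        defaults to the canonical taxonomy where names match it.

    A network empty in either variant yields a flagged row with NaN Dice
    rather than a silently dropped pair.
    """
    if len(variants) < 2:
        raise ValueError("need at least two atlas variants")
    if network_class is None:
        network_class = NETWORK_CLASS
    labels = {name: (v.network_label if hasattr(v, "network_label") else
                     np.asarray(v))
              for name, v in variants.items()}
    shapes = {a.shape for a in labels.values()}
    if len(shapes) != 1:
        raise ValueError("all variants must share one element grid")

    rows = []
    for va, vb in itertools.combinations(sorted(labels), 2):
        fam_a = atlas_family_of_variant[va]
        fam_b = atlas_family_of_variant[vb]
        pair_class = "intra-atlas" if fam_a == fam_b else "inter-atlas"
        for lab, net in sorted(network_names.items()):
            mask_a = labels[va] == lab
            mask_b = labels[vb] == lab
            missing = not mask_a.any() or not mask_b.any()
            d = np.nan if (not mask_a.any() and not mask_b.any()) \
                else dice(mask_a, mask_b)
            rows.append({
                "network_name": net, "variant_a": va, "variant_b": vb,
                "dsc": d, "pair_class": pair_class,
                "network_class": network_class.get(net, "unclassified"),
                "missing_in_variant": missing,
            })
    return pd.DataFrame(rows)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney test; W is the Mann-Whitney U of ``x``.

    W = (rank sum of x) - n_x(n_x+1)/2.  The two-sided p-value is exact for
    small samples without ties (n_x + n_y <= 25) and uses the normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = x.size + y.size <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on k-1 df.

    All values identical across all groups is the degenerate no-signal case:
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    if np.unique(np.concatenate(groups)).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, p * m); order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)
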