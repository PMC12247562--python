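"""From motion traces and node time series to within-network RSFC T-scores.

Implements the motion-exclusion rule (mean framewise displacement more than
3 unscaled median absolute deviations above the median), joint nuisance
regression and 0.01-0.1 Hz bandpass filtering, within-network averaging of
node-pairwise correlations, and the T-score standardization (mean 50, SD 10
at the baseline occasion, per atlas x network stratum).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from nilearn import signal as nisignal


def framewise_displacement(trace: np.ndarray,
                           head_radius_mm: float = 50.0) -> np.ndarray:
    """Per-frame framewise displacement of a six-parameter motion trace.

    FD_t = sum |delta translation| + head_radius * sum |delta rotation|
    (rotations in radians converted to arc length on a 50 mm sphere);
    FD of the first frame is 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("trace must be (n_frames, 6)")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.isfinite(trace).all():
        raise ValueError("motion parameters must be finite")
    d = np.abs(np.diff(trace, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def flag_high_motion(mean_fd_per_scan) -> np.ndarray:
    """Flag scans whose mean FD is strictly above median + 3*MAD.

    MAD is the raw median absolute deviation (no 1.4826 consistency
    constant).  With all-equal values MAD is 0 and nothing exceeds the
    median strictly, so nothing is flagged.
    """
    fd = np.asarray(mean_fd_per_scan, dtype=float)
    if fd.size < 3:
        raise ValueError("need at least 3 scans for the outlier rule")
    med = np.median(fd)
    mad = np.median(np.abs(fd - med))
    return fd > med + 3.0 * mad


def clean_series(node_series: np.ndarray, confounds: np.ndarray | None,
                 band: tuple = (0.01, 0.1), tr_seconds: float = 2.0
                 ) -> np.ndarray:
    """Joint confound regression and bandpass filtering of node series.

    The confounds are band-filtered to the same passband before regression
    (so that regression does not reintroduce out-of-band artifacts), which is
    what nilearn's Butterworth cleaning does under the hood.  ``band=None``
    skips filtering and performs confound regression alone.  Collinear
    confound columns are dropped with a warning.  Output rows (nodes) are
    exactly zero-mean.
    """
    series = np.asarray(node_series, dtype=float)
    if series.ndim != 2:
        raise ValueError("node_series must be (n_nodes, n_timepoints)")
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != series.shape[1]:
            raise ValueError("confound rows must align with the time axis")
        if np.linalg.matrix_rank(confounds) < confounds.shape[1]:
            warnings.warn("dropping collinear confound columns")
            # keep a maximal independent subset, greedily left to right
            keep: list[int] = []
            basis = np.empty((confounds.shape[0], 0))
            for j in range(confounds.shape[1]):
                col = confounds[:, j]
                resid = col if basis.shape[1] == 0 else col - basis @ \
                    np.linalg.lstsq(basis, col, rcond=None)[0]
                if np.linalg.norm(resid) > 1e-8 * max(
                        1.0, np.linalg.norm(col)):
                    keep.append(j)
                    basis = np.column_stack([basis, col])
            confounds = confounds[:, keep]
    if band is None:
        cleaned = nisignal.clean(
            series.T, confounds=confounds, detrend=False, standardize=None,
            t_r=tr_seconds, filter=False).T
    else:
        low, high = band
        cleaned = nisignal.clean(
            series.T, confounds=confounds, detrend=False, standardize=None,
            low_pass=high, high_pass=low, t_r=tr_seconds,
            filter="butterworth").T
    return cleaned - cleaned.mean(axis=1, keepdims=True)


def within_network_rsfc(corr: np.ndarray, node_set) -> float:
    """Mean off-diagonal correlation among the nodes of one network."""
    corr = np.asarray(corr, dtype=float)
    idx = np.asarray(list(node_set), dtype=int)
    if idx.size < 2:
        raise ValueError("within-network RSFC needs at least 2 nodes")
    sub = corr[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def extract_network_rsfc(element_series: np.ndarray, parc) -> dict:
    """Per-network mean RSFC from element series and a parcellation.

    Node series are element averages; node-pairwise Pearson correlations are
    averaged over each network's node pairs.  Networks with fewer than two
    nodes are skipped.
    """
    node_to_net = parc.network_of_node()
    nodes = sorted(node_to_net)
    node_series = np.vstack([
        element_series[parc.node_label == nd].mean(axis=0) for nd in nodes])
    corr = np.corrcoef(node_series)
    out = {}
    for net in range(1, parc.n_networks + 1):
        members = [i for i, nd in enumerate(nodes) if node_to_net[nd] == net]
        if len(members) >= 2:
            out[net] = within_network_rsfc(corr, members)
    return out


def tscore_standardize(panel: pd.DataFrame, baseline_occasion: int = 0,
                       value_col: str = "rsfc_t") -> pd.DataFrame:
    """T-score standardization per (atlas, network) stratum.

    Within each stratum the baseline mean and SD (across subjects with a
    non-missing baseline, sample SD) define an affine map z -> 50 + 10 z
    applied to every occasion, so each stratum has mean 50 / SD 10 at
    baseline by construction.  Subjects lacking a baseline are standardized
    by the same stratum constants.
    """
    out = panel.copy()

    def _std(group: pd.DataFrame) -> pd.DataFrame:
        base = group.loc[group["occasion"] == baseline_occasion, value_col]
        base = base.dropna()
        if base.size < 2:
            raise ValueError("need >=2 non-missing baseline values per "
                             "(atlas, network) stratum")
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            raise ValueError("zero baseline SD in a stratum")
        group = group.copy()
        group[value_col] = 50.0 + 10.0 * (group[value_col] - mu) / sd
        return group

    pieces = [_std(g) for _, g in out.groupby(["atlas", "network"],
                                              sort=False)]
    return pd.concat(pieces).sort_index()
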