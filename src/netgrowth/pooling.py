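"""Inverse-variance pooling of per-atlas growth-model effects.

When the selected models agree across atlases on the trajectory shape, the
per-atlas estimates of an effect (linear slope, quadratic slope, age effect
on intercept or slope) are combined with fixed-effect precision weights
w_j = 1 / SE_j^2.  Effects absent from some selected model (e.g. an age
effect on the slope when no slope variance was estimated) are not poolable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: effect name -> parameter name in an LGC fit
EFFECT_PARAMS = {
    "linear slope": "mean_linear",
    "quadratic slope": "mean_quadratic",
    "age on intercept": "age0_on_intercept",
    "age on linear slope": "age0_on_linear",
}


@dataclass
class PooledEffect:
    effect: str
    estimates: np.ndarray
    ses: np.ndarray
    pooled: float
    pooled_se: float
    ci95: tuple
    significant: bool


def pooled_effect(estimates, ses, effect: str = "") -> PooledEffect:
    """Fixed-effect inverse-variance pooled estimate.

    weights w_j = 1/SE_j^2; pooled = sum(w e)/sum(w);
    pooled SE = sqrt(1/sum w); 95% CI = pooled +/- 1.96 SE; significant iff
    the CI excludes zero.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size != se.size or est.size < 2:
        raise ValueError("need >=2 estimates with matching SEs")
    if np.any(se <= 0) or not np.isfinite(se).all():
        raise ValueError("all SEs must be positive and finite")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(math.sqrt(1.0 / np.sum(w)))
    lo, hi = pooled - 1.96 * pooled_se, pooled + 1.96 * pooled_se
    return PooledEffect(effect=effect, estimates=est, ses=se, pooled=pooled,
                        pooled_se=pooled_se, ci95=(lo, hi),
                        significant=not (lo <= 0.0 <= hi))


def _shape(fit) -> str:
    return "quadratic" if fit.spec.n_factors == 3 else "linear"


def pool_study(selected_fits: dict) -> pd.DataFrame:
    """Pool effects across atlases for each network.

    ``selected_fits`` maps network -> {atlas: selected LGCFit}.  Pooling is
    attempted only where every atlas's selected model implies the same
    trajectory shape; otherwise the network is marked non-poolable.  Within
    a poolable network, each effect is pooled only if its parameter exists
    (with a finite SE) in every selected model.

    Returns a tidy table with one row per network x effect: pooled estimate,
    SE, CI bounds, significance, and a ``poolable``/``reason`` audit.
    """
    rows = []
    for network, fits_by_atlas in selected_fits.items():
        fits = list(fits_by_atlas.values())
        if len(fits) < 2:
            raise ValueError(f"network {network!r}: need >=2 atlases to pool")
        shapes = {_shape(f) for f in fits}
        if len(shapes) > 1:
            for effect in EFFECT_PARAMS:
                rows.append(dict(network=network, effect=effect,
                                 poolable=False,
                                 reason="trajectory shape disagreement",
                                 pooled=np.nan, pooled_se=np.nan,
                                 ci_low=np.nan, ci_high=np.nan,
                                 significant=False))
            continue
        for effect, pname in EFFECT_PARAMS.items():
            present = all(
                pname in f.estimates
                and np.isfinite(f.standard_errors.get(pname, np.nan))
                for f in fits)
            if not present:
                rows.append(dict(network=network, effect=effect,
                                 poolable=False,
                                 reason="effect absent from a selected model",
                                 pooled=np.nan, pooled_se=np.nan,
                                 ci_low=np.nan, ci_high=np.nan,
                                 significant=False))
                continue
            pe = pooled_effect([f.estimates[pname] for f in fits],
                               [f.standard_errors[pname] for f in fits],
                               effect=effect)
            rows.append(dict(network=network, effect=effect, poolable=True,
                             reason="", pooled=pe.pooled,
                             pooled_se=pe.pooled_se, ci_low=pe.ci95[0],
                             ci_high=pe.ci95[1], significant=pe.significant))
    return pd.DataFrame(rows)
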