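"""Reading and writing the pipeline's on-disk formats.

Parcellations travel as NIfTI integer label volumes or per-vertex label
tables (CSV); panels as tidy CSV; fits as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_parcellation_nifti(label_volume: np.ndarray, path,
                             affine: np.ndarray | None = None) -> None:
    """Write a 3D integer label volume as NIfTI (int32 datatype)."""
    vol = np.asarray(label_volume)
    if vol.ndim != 3:
        raise ValueError("label volume must be 3D")
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(vol.astype(np.int32), affine)
    nib.save(img, str(path))


def read_parcellation_nifti(path) -> np.ndarray:
    """Read a NIfTI label volume, rounding to integers."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj).round().astype(np.int32)


def write_vertex_labels(parc, path) -> None:
    """Per-vertex label table (vertex, network, node) as CSV."""
    pd.DataFrame({
        "vertex": np.arange(parc.n_elements),
        "network": parc.network_label,
        "node": parc.node_label,
    }).to_csv(path, index=False)


def read_vertex_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("vertex", "network", "node"):
        if col not in df.columns:
            raise ValueError(f"vertex label table lacks column {col!r}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, float_format="%.10g")


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)


def fit_to_dict(fit) -> dict:
    """JSON-serializable summary of an LGC fit."""
    out = {
        "variant": fit.spec.variant_id,
        "estimates": {k: float(v) for k, v in fit.estimates.items()},
        "standard_errors": {k: float(v)
                            for k, v in fit.standard_errors.items()},
        "ci95": {k: [float(v[0]), float(v[1])]
                 for k, v in fit.ci95.items()},
        "loglik": float(fit.loglik),
        "n_subjects": int(fit.n_subjects),
        "converged": bool(fit.converged),
        "heywood": bool(fit.heywood),
    }
    if fit.fit is not None:
        out["fit_indices"] = {k: (float(v) if np.isfinite(v) else None)
                              for k, v in fit.fit.to_dict().items()}
    return out


def write_fits_json(fits_nested: dict, path) -> None:
    Path(path).write_text(json.dumps(fits_nested, indent=2, sort_keys=True))
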