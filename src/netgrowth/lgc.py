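"""Latent growth curve models estimated by full-information ML.

Five model variants of increasing complexity describe within-network RSFC
T-scores over five occasions at elapsed years (0, 1, 2, 4, 7):

1. intercept + linear slope, fixed effects only (no latent variance),
2. + intercept variance and covariate regressions on the intercept,
3. + linear-slope variance, intercept-slope covariance, covariates on both,
4. intercept + linear + quadratic slope, intercept variance only,
   covariates on the intercept,
5. the full quadratic model: all three factor variances and covariances
   free, covariates on all factors.

Loadings are fixed: ones for the intercept, the elapsed years for the
linear slope, and their squares for the quadratic slope.  Residual means
are zero and a single residual variance theta is shared across occasions.
Covariates are baseline age (mean-centered), sex (0 = female) and a
3-level education code.

Estimation maximizes the casewise (full-information) Gaussian likelihood,
so subjects contribute whichever occasions they were observed at; this is
the standard missing-at-random treatment.  Variances enter the optimizer
untransformed, so inadmissible (Heywood) solutions can occur and are
flagged rather than prevented, mirroring common SEM software.  Model
selection counts "good" fit indicators (chi2/df <= 2, p > 0.05,
CFI > 0.97, RMSEA <= 0.05, no Heywood case) and breaks ties by BIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from .synthetic import DEFAULT_SCHEDULE

FACTOR_NAMES = ("intercept", "linear", "quadratic")
COVARIATE_NAMES = ("age0", "sex", "education")

_LN2PI = math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LGCSpec:
    """Definition of one latent growth curve variant."""

    variant_id: int
    occasions: tuple
    n_factors: int
    free_variances: tuple      # factor indices with free variance
    free_covariances: tuple    # (i, j) factor pairs with free covariance
    covariate_factors: tuple   # factor indices receiving covariate paths

    def __post_init__(self):
        for i, j in self.free_covariances:
            if i not in self.free_variances or j not in self.free_variances:
                raise ValueError("a free covariance needs both variances free")

    def loadings(self) -> np.ndarray:
        t = np.asarray(self.occasions, dtype=float)
        cols = [np.ones_like(t), t, t**2][: self.n_factors]
        return np.column_stack(cols)

    @property
    def factor_names(self) -> tuple:
        return FACTOR_NAMES[: self.n_factors]

    def param_names(self) -> list:
        names = [f"mean_{FACTOR_NAMES[f]}" for f in range(self.n_factors)]
        for f in self.covariate_factors:
            for c in COVARIATE_NAMES:
                names.append(f"{c}_on_{FACTOR_NAMES[f]}")
        for f in self.free_variances:
            names.append(f"var_{FACTOR_NAMES[f]}")
        for i, j in self.free_covariances:
            names.append(f"cov_{FACTOR_NAMES[i]}_{FACTOR_NAMES[j]}")
        names.append("resid_var")
        return names

    @property
    def n_free_params(self) -> int:
        return len(self.param_names())


_VARIANTS = {
    1: dict(n_factors=2, free_variances=(), free_covariances=(),
            covariate_factors=()),
    2: dict(n_factors=2, free_variances=(0,), free_covariances=(),
            covariate_factors=(0,)),
    3: dict(n_factors=2, free_variances=(0, 1), free_covariances=((0, 1),),
            covariate_factors=(0, 1)),
    4: dict(n_factors=3, free_variances=(0,), free_covariances=(),
            covariate_factors=(0,)),
    5: dict(n_factors=3, free_variances=(0, 1, 2),
            free_covariances=((0, 1), (0, 2), (1, 2)),
            covariate_factors=(0, 1, 2)),
}


def build_lgc_spec(variant_id: int,
                   occasions=tuple(DEFAULT_SCHEDULE)) -> LGCSpec:
    """Spec for one of the five canonical variants (see module docstring)."""
    if variant_id not in _VARIANTS:
        raise ValueError(f"unknown variant {variant_id}; expected 1..5")
    return LGCSpec(variant_id=variant_id, occasions=tuple(occasions),
                   **_VARIANTS[variant_id])


def params_to_dict(spec: LGCSpec, params: np.ndarray) -> dict:
    return dict(zip(spec.param_names(), np.asarray(params, dtype=float)))


def params_from_dict(spec: LGCSpec, d: dict) -> np.ndarray:
    return np.array([d[name] for name in spec.param_names()])


def _unpack(spec: LGCSpec, params: np.ndarray):
    """Split a parameter vector into alpha, Gamma, Psi, theta."""
    params = np.asarray(params, dtype=float)
    q = spec.n_factors
    pos = 0
    alpha = params[pos:pos + q]
    pos += q
    gamma = np.zeros((q, 3))
    for f in spec.covariate_factors:
        gamma[f] = params[pos:pos + 3]
        pos += 3
    psi = np.zeros((q, q))
    for f in spec.free_variances:
        psi[f, f] = params[pos]
        pos += 1
    for i, j in spec.free_covariances:
        psi[i, j] = psi[j, i] = params[pos]
        pos += 1
    theta = params[pos]
    return alpha, gamma, psi, theta


def model_moments(spec: LGCSpec, params, covariate_values=None):
    """Model-implied mean vector and covariance over the occasions.

    cov = Lambda Psi Lambda' + theta I; mean = Lambda (alpha + Gamma x)
    for covariate vector x (zero if omitted).
    """
    if isinstance(params, dict):
        params = params_from_dict(spec, params)
    alpha, gamma, psi, theta = _unpack(spec, params)
    lam = spec.loadings()
    x = np.zeros(3) if covariate_values is None \
        else np.asarray(covariate_values, dtype=float)
    mean = lam @ (alpha + gamma @ x)
    cov = lam @ psi @ lam.T + theta * np.eye(lam.shape[0])
    return mean, cov


# --------------------------------------------------------------------------
# generic FIML machinery: mean linear in params with per-subject covariate
# design, covariance linear in params
# --------------------------------------------------------------------------

class _GaussianStructure:
    """Gaussian model with mu_i = (T0 + sum_c x_ic T_c) m  and
    Sigma = sum_j c_j D_j; both linear in the free parameters, which makes
    the casewise likelihood gradient cheap."""

    def __init__(self, T0, T_list, D_list, names, n_occasions):
        self.T0 = np.asarray(T0, dtype=float)
        self.T_list = [np.asarray(T, dtype=float) for T in T_list]
        self.D_list = [np.asarray(D, dtype=float) for D in D_list]
        self.names = list(names)
        self.k_full = n_occasions
        self.n_mean = self.T0.shape[1]
        self.n_cov = len(self.D_list)
        self.n_params = self.n_mean + self.n_cov

    def sigma(self, cpar):
        out = np.zeros((self.k_full, self.k_full))
        for c, D in zip(cpar, self.D_list):
            out += c * D
        return out


def _lgc_structure(spec: LGCSpec) -> _GaussianStructure:
    lam = spec.loadings()
    k, q = lam.shape
    mean_cols = [lam[:, f] for f in range(q)]
    T_list = [np.zeros((k, 0)) for _ in COVARIATE_NAMES]
    gamma_cols: list = []
    for f in spec.covariate_factors:
        for ci in range(3):
            gamma_cols.append((f, ci))
    n_mean = q + len(gamma_cols)
    T0 = np.zeros((k, n_mean))
    T0[:, :q] = np.column_stack(mean_cols)
    T_list = [np.zeros((k, n_mean)) for _ in range(3)]
    for col, (f, ci) in enumerate(gamma_cols, start=q):
        T_list[ci][:, col] = lam[:, f]
    if not gamma_cols:
        T_list = []
    D_list = []
    for f in spec.free_variances:
        D_list.append(np.outer(lam[:, f], lam[:, f]))
    for i, j in spec.free_covariances:
        D_list.append(np.outer(lam[:, i], lam[:, j])
                      + np.outer(lam[:, j], lam[:, i]))
    D_list.append(np.eye(k))
    return _GaussianStructure(T0, T_list, D_list, spec.param_names(), k)


def _saturated_structure(k: int, with_covariates: bool) -> _GaussianStructure:
    names = [f"mu_{t}" for t in range(k)]
    T0 = np.eye(k)
    T_list = []
    if with_covariates:
        for c in COVARIATE_NAMES:
            names += [f"{c}_on_y{t}" for t in range(k)]
        n_mean = k * 4
        T0 = np.zeros((k, n_mean))
        T0[:, :k] = np.eye(k)
        T_list = []
        for ci in range(3):
            T = np.zeros((k, n_mean))
            T[:, (ci + 1) * k:(ci + 2) * k] = np.eye(k)
            T_list.append(T)
    D_list = []
    for i in range(k):
        for j in range(i, k):
            D = np.zeros((k, k))
            if i == j:
                D[i, i] = 1.0
                names.append(f"var_y{i}")
            else:
                D[i, j] = D[j, i] = 1.0
                names.append(f"cov_y{i}_y{j}")
            D_list.append(D)
    return _GaussianStructure(T0, T_list, D_list, names, k)


def _independence_structure(k: int) -> _GaussianStructure:
    names = [f"mu_{t}" for t in range(k)] + [f"var_y{t}" for t in range(k)]
    D_list = []
    for i in range(k):
        D = np.zeros((k, k))
        D[i, i] = 1.0
        D_list.append(D)
    return _GaussianStructure(np.eye(k), [], D_list, names, k)


@dataclass
class _Pattern:
    idx: np.ndarray     # observed occasion indices
    Y: np.ndarray       # (n_i, k_i) observed outcomes
    X: np.ndarray       # (n_i, 3) covariates
    # structure-specific precomputed slices (set by _compile)
    Dsub: np.ndarray | None = None     # (n_covparams, k_i, k_i)
    T0sub: np.ndarray | None = None    # (k_i, n_meanparams)
    Tcsub: list | None = None


def panel_to_arrays(panel: pd.DataFrame, value_col: str = "rsfc_t"):
    """Tidy panel -> (y wide (n, occasions), X (n, 3), subject ids).

    Expects one row per subject x occasion for a single (atlas, network)
    dataset; missing outcomes as NaN.  Covariates must be complete and
    time-invariant.
    """
    for col in ("subject_id", "occasion", value_col):
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    if panel.duplicated(["subject_id", "occasion"]).any():
        raise ValueError("panel has duplicate (subject, occasion) records; "
                         "filter to one atlas x network dataset first")
    wide = panel.pivot(index="subject_id", columns="occasion",
                       values=value_col).sort_index()
    occs = sorted(panel["occasion"].unique())
    wide = wide.reindex(columns=occs)
    cov = panel.drop_duplicates("subject_id").set_index(
        "subject_id").sort_index()
    X = np.column_stack([
        cov[c].to_numpy(dtype=float) if c in cov.columns else
        np.zeros(len(cov)) for c in COVARIATE_NAMES])
    if not np.isfinite(X).all():
        raise ValueError("covariates must be complete")
    return wide.to_numpy(dtype=float), X, wide.index.to_numpy()


def _build_patterns(y: np.ndarray, X: np.ndarray) -> list:
    obs = np.isfinite(y)
    if (~obs).all(axis=1).any():
        raise ValueError("every subject needs at least one observed occasion")
    patterns = []
    keys = [tuple(row) for row in obs]
    for key in sorted(set(keys), reverse=True):
        rows = np.array([k == key for k in keys])
        idx = np.flatnonzero(np.array(key))
        patterns.append(_Pattern(idx=idx, Y=y[np.ix_(rows, idx)],
                                 X=X[rows]))
    return patterns


def _compile(struct: _GaussianStructure, patterns: list) -> list:
    """Attach structure-specific slices to each missingness pattern."""
    out = []
    for pat in patterns:
        ix = np.ix_(pat.idx, pat.idx)
        out.append(_Pattern(
            idx=pat.idx, Y=pat.Y, X=pat.X,
            Dsub=np.stack([D[ix] for D in struct.D_list]),
            T0sub=struct.T0[pat.idx],
            Tcsub=[T[pat.idx] for T in struct.T_list]))
    return out


def _nll_grad(params, patterns, struct: _GaussianStructure, scale: float):
    """Negative average loglik per subject and its gradient.

    ``patterns`` must have been processed by :func:`_compile` for this
    structure.
    """
    m = struct.n_mean
    mpar, cpar = params[:m], params[m:]
    ll = 0.0
    gm = np.zeros(m)
    gc = np.zeros(struct.n_cov)
    for pat in patterns:
        k = pat.idx.size
        n = pat.Y.shape[0]
        sp = np.tensordot(cpar, pat.Dsub, axes=(0, 0))
        try:
            cf = sla.cho_factor(sp, lower=True)
        except (sla.LinAlgError, ValueError):
            lam_min = float(np.linalg.eigvalsh(sp).min())
            return 1e8 * (1.0 + max(0.0, -lam_min)), np.zeros_like(params)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        mu = (pat.T0sub @ mpar)[None, :]
        for ci, t in enumerate(pat.Tcsub):
            mu = mu + pat.X[:, ci:ci + 1] * (t @ mpar)[None, :]
        r = pat.Y - mu                       # (n, k)
        sinv_rt = sla.cho_solve(cf, r.T)     # (k, n)
        quad = float(np.sum(r.T * sinv_rt))
        ll += -0.5 * (n * (k * _LN2PI + logdet) + quad)
        sinv = sla.cho_solve(cf, np.eye(k))
        g_sigma = 0.5 * (sinv_rt @ sinv_rt.T - n * sinv)
        gc += np.tensordot(pat.Dsub, g_sigma, axes=([1, 2], [0, 1]))
        s_sum = sinv_rt.sum(axis=1)          # (k,)
        gm += pat.T0sub.T @ s_sum
        if pat.Tcsub:
            u = sinv_rt @ pat.X              # (k, 3)
            for ci, t in enumerate(pat.Tcsub):
                gm += t.T @ u[:, ci]
    grad = np.concatenate([gm, gc])
    return -ll / scale, -grad / scale


def fiml_loglik(spec: LGCSpec, params, panel) -> float:
    """Casewise (full-information) Gaussian log-likelihood of a panel.

    Each subject contributes the log-density of their observed occasions
    under the marginal of the model-implied moments.  ``panel`` may be a
    tidy DataFrame or a ``(y, X)`` pair of arrays.
    """
    if isinstance(params, dict):
        params = params_from_dict(spec, params)
    y, X = _coerce_panel(panel)
    patterns = _build_patterns(y, X)
    struct = _lgc_structure(spec)
    compiled = _compile(struct, patterns)
    nll, _ = _nll_grad(np.asarray(params, float), compiled, struct, 1.0)
    if nll >= 1e8:  # implied covariance singular on an observed pattern
        warnings.warn("implied covariance not positive definite for an "
                      "observed missingness pattern; loglik is -inf")
        return float("-inf")
    return -nll


def _coerce_panel(panel):
    if isinstance(panel, pd.DataFrame):
        y, X, _ = panel_to_arrays(panel)
        return y, X
    y, X = panel
    return np.asarray(y, dtype=float), np.asarray(X, dtype=float)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2: float
    df: int
    p_chi2: float
    chi2_over_df: float
    cfi: float
    rmsea: float
    bic: float
    n_good_indicators: int
    n_acceptable_indicators: int = 0
    rmsea_undefined: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "chi2", "df", "p_chi2", "chi2_over_df", "cfi", "rmsea", "bic",
            "n_good_indicators", "n_acceptable_indicators")}


@dataclass
class LGCFit:
    """Result of estimating one LGC variant on one panel."""

    spec: LGCSpec
    estimates: dict
    standard_errors: dict
    ci95: dict
    loglik: float
    n_subjects: int
    converged: bool
    heywood: bool
    fit: FitIndices | None = None
    grad_norm: float = float("nan")

    @property
    def n_params(self) -> int:
        return self.spec.n_free_params

    @property
    def has_covariates(self) -> bool:
        return bool(self.spec.covariate_factors)

    def params_vector(self) -> np.ndarray:
        return params_from_dict(self.spec, self.estimates)


@dataclass
class BaselineFit:
    """Saturated or independence reference fit (loglik + parameter count)."""

    kind: str
    loglik: float
    n_params: int
    converged: bool
    estimates: dict = field(default_factory=dict)


def _start_values(spec: LGCSpec, y: np.ndarray) -> np.ndarray:
    lam = spec.loadings()
    ybar = np.nanmean(y, axis=0)
    alpha0, *_ = np.linalg.lstsq(lam, ybar, rcond=None)
    vbar = float(np.nanmean(np.nanvar(y, axis=0, ddof=1)))
    vbar = max(vbar, 1e-3)
    start = list(alpha0)
    start += [0.0] * (3 * len(spec.covariate_factors))
    scale_by_factor = {0: 0.4 * vbar, 1: 0.02 * vbar, 2: 0.002 * vbar}
    for f in spec.free_variances:
        start.append(scale_by_factor[f])
    start += [0.0] * len(spec.free_covariances)
    start.append(0.5 * vbar)
    return np.array(start)


def _fd_hessian(fun_grad, x, args):
    """Hessian of a scalar function from central differences of its
    analytic gradient."""
    p = x.size
    H = np.zeros((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fun_grad(xp, *args)
        _, gm = fun_grad(xm, *args)
        H[:, i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _optimize(struct, patterns, x0, n_subjects, pgtol=1e-8, maxiter=1000):
    """Maximize the per-subject average loglik.

    Quasi-Newton (L-BFGS) to a moderate gradient tolerance, then Newton
    polish with the observed-information Hessian down to ``pgtol`` on the
    max-abs gradient of the per-subject objective.  Returns the final
    Hessian too so standard errors can reuse it.
    """
    compiled = _compile(struct, patterns)
    args = (compiled, struct, float(n_subjects))
    res = optimize.minimize(
        _nll_grad, np.asarray(x0, float), args=args, jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-5})
    x, f = res.x, res.fun
    H = None
    _, g = _nll_grad(x, *args)
    for _ in range(20):
        if np.max(np.abs(g)) < pgtol:
            break
        H = _fd_hessian(_nll_grad, x, args)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g
        if not np.isfinite(step).all():
            step = g
        # backtracking on the Newton direction
        t = 1.0
        for _ in range(30):
            f_new, g_new = _nll_grad(x - t * step, *args)
            if f_new <= f + 1e-12 * abs(f):
                break
            t *= 0.5
        else:
            break
        if f_new > f:
            break
        x, f, g = x - t * step, f_new, g_new
    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm < max(pgtol, 1e-5)
    loglik = -f * n_subjects
    return x, loglik, converged, grad_norm, H


def _observed_information(struct, patterns, xhat, n_subjects):
    """Numerically differentiate the analytic gradient (central differences)."""
    compiled = _compile(struct, patterns)
    p = xhat.size
    H = np.zeros((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(xhat[i]))
        xp, xm = xhat.copy(), xhat.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = _nll_grad(xp, compiled, struct, float(n_subjects))
        _, gm = _nll_grad(xm, compiled, struct, float(n_subjects))
        H[:, i] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T) * n_subjects  # back to raw-loglik scale
    return H


def detect_heywood(fit: "LGCFit") -> bool:
    """Inadmissible solution: a negative estimated variance (latent or
    residual) or an implied latent correlation outside [-1, 1]."""
    spec, est = fit.spec, fit.estimates
    variances = {f: est[f"var_{FACTOR_NAMES[f]}"]
                 for f in spec.free_variances}
    if any(v < 0 for v in variances.values()):
        return True
    if est["resid_var"] < 0:
        return True
    for i, j in spec.free_covariances:
        vi, vj = variances[i], variances[j]
        if vi <= 0 or vj <= 0:
            return True
        c = est[f"cov_{FACTOR_NAMES[i]}_{FACTOR_NAMES[j]}"]
        if abs(c) > math.sqrt(vi * vj) * (1.0 + 1e-12):
            return True
    return False


def fit_lgc(spec: LGCSpec, panel, pgtol: float = 1e-8,
            compute_se: bool = True) -> LGCFit:
    """Estimate an LGC variant by FIML with method-of-moments start values.

    Deterministic given the data (quasi-Newton from fixed starts).  Standard
    errors come from the inverse observed information, evaluated numerically
    from the analytic gradient; 95% CIs are estimate +/- 1.96 SE.
    """
    y, X = _coerce_panel(panel)
    patterns = _build_patterns(y, X)
    struct = _lgc_structure(spec)
    x0 = _start_values(spec, y)
    n = y.shape[0]
    xhat, loglik, converged, grad_norm, H_scaled = _optimize(
        struct, patterns, x0, n, pgtol=pgtol)
    names = spec.param_names()
    estimates = dict(zip(names, xhat))
    ses = {k: float("nan") for k in names}
    if compute_se and converged:
        H = (H_scaled * n if H_scaled is not None else
             _observed_information(struct, patterns, xhat, n))
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            ses = {k: (math.sqrt(v) if v > 0 else float("nan"))
                   for k, v in zip(names, d)}
        except np.linalg.LinAlgError:
            pass
    ci = {k: (estimates[k] - 1.96 * ses[k], estimates[k] + 1.96 * ses[k])
          for k in names}
    fit = LGCFit(spec=spec, estimates=estimates, standard_errors=ses,
                 ci95=ci, loglik=loglik, n_subjects=n, converged=converged,
                 heywood=False, grad_norm=grad_norm)
    fit.heywood = detect_heywood(fit)
    return fit


def fit_baselines(panel, with_covariates: bool = False,
                  pgtol: float = 1e-8) -> tuple:
    """Saturated and independence reference fits for the fit indices.

    The saturated model frees the per-occasion means and the full occasion
    covariance; when the candidate model includes covariates the saturated
    mean structure additionally frees all per-occasion covariate slopes
    (fixed-x convention).  The independence baseline frees means and
    variances only (covariances and covariate slopes zero).
    """
    y, X = _coerce_panel(panel)
    patterns = _build_patterns(y, X)
    k = y.shape[1]
    n = y.shape[0]

    mu0 = np.nanmean(y, axis=0)
    var0 = np.nanvar(y, axis=0, ddof=1)
    cov0 = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            both = np.isfinite(y[:, i]) & np.isfinite(y[:, j])
            if both.sum() > 2:
                cov0[i, j] = np.cov(y[both, i], y[both, j])[0, 1]
            elif i == j:
                cov0[i, j] = max(var0[i], 1e-3)
    w, v = np.linalg.eigh(0.5 * (cov0 + cov0.T))
    cov0 = (v * np.maximum(w, 1e-3)) @ v.T

    sat = _saturated_structure(k, with_covariates)
    if with_covariates:
        # available-case OLS per occasion: near the FIML solution, so the
        # optimizer only has to mop up the missing-data correction
        a0 = mu0.copy()
        b0 = np.zeros((k, 3))
        resid = np.full_like(y, np.nan)
        for t in range(k):
            rows = np.isfinite(y[:, t])
            if rows.sum() > 5:
                design = np.column_stack([np.ones(rows.sum()), X[rows]])
                beta, *_ = np.linalg.lstsq(design, y[rows, t], rcond=None)
                a0[t], b0[t] = beta[0], beta[1:]
                resid[rows, t] = y[rows, t] - design @ beta
        rcov = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                both = np.isfinite(resid[:, i]) & np.isfinite(resid[:, j])
                if both.sum() > 2:
                    rcov[i, j] = np.cov(resid[both, i], resid[both, j])[0, 1]
                elif i == j:
                    rcov[i, j] = max(var0[i], 1e-3)
        w, v = np.linalg.eigh(0.5 * (rcov + rcov.T))
        rcov = (v * np.maximum(w, 1e-3)) @ v.T
        x0 = np.concatenate([a0, b0.T.ravel(), rcov[np.triu_indices(k)]])
    else:
        x0 = np.concatenate([mu0, cov0[np.triu_indices(k)]])
    xs, ll_s, conv_s, _, _ = _optimize(sat, patterns, x0, n, pgtol=pgtol)
    sat_fit = BaselineFit("saturated", ll_s, sat.n_params, conv_s,
                          dict(zip(sat.names, xs)))

    ind = _independence_structure(k)
    x0 = np.concatenate([mu0, np.maximum(var0, 1e-3)])
    xi, ll_i, conv_i, _, _ = _optimize(ind, patterns, x0, n, pgtol=pgtol)
    ind_fit = BaselineFit("independence", ll_i, ind.n_params, conv_i,
                          dict(zip(ind.names, xi)))
    return sat_fit, ind_fit


GOOD_THRESHOLDS = dict(chi2_over_df=2.0, p_chi2=0.05, cfi=0.97, rmsea=0.05)
ACCEPTABLE_THRESHOLDS = dict(chi2_over_df=3.0, p_chi2=0.01, cfi=0.95,
                             rmsea=0.08)


def compute_fit_indices(fit: LGCFit, saturated: BaselineFit,
                        independence: BaselineFit,
                        n_subjects: int | None = None) -> FitIndices:
    """Chi-square, CFI, RMSEA, BIC and the good-indicator count.

    chi2 = 2 (ll_sat - ll_model) with df = k_sat - k_model;
    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m n)); BIC = -2 ll + k ln n.
    The good-indicator count adds one for each of the four thresholds met
    plus one for the absence of a Heywood case (0..5).
    """
    if not (fit.converged and saturated.converged and independence.converged):
        raise ValueError("fit indices need all three fits converged")
    n = fit.n_subjects if n_subjects is None else n_subjects
    chi2 = max(2.0 * (saturated.loglik - fit.loglik), 0.0)
    df = saturated.n_params - fit.n_params
    if df < 0:
        raise ValueError("model has more parameters than the saturated model")
    chi2_b = max(2.0 * (saturated.loglik - independence.loglik), 0.0)
    df_b = saturated.n_params - independence.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea_undef = df == 0
    if df > 0:
        ratio = chi2 / df
        rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * n))
    else:
        ratio = 0.0 if chi2 <= 1e-8 else float("inf")
        rmsea = 0.0
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    cfi = min(max(cfi, 0.0), 1.0)
    bic = -2.0 * fit.loglik + fit.n_params * math.log(n)
    good = int(ratio <= GOOD_THRESHOLDS["chi2_over_df"]) \
        + int(p > GOOD_THRESHOLDS["p_chi2"]) \
        + int(cfi > GOOD_THRESHOLDS["cfi"]) \
        + int(rmsea <= GOOD_THRESHOLDS["rmsea"]) \
        + int(not fit.heywood)
    # the looser "acceptable" band is reported but plays no role in selection
    acceptable = int(ratio <= ACCEPTABLE_THRESHOLDS["chi2_over_df"]) \
        + int(p > ACCEPTABLE_THRESHOLDS["p_chi2"]) \
        + int(cfi > ACCEPTABLE_THRESHOLDS["cfi"]) \
        + int(rmsea <= ACCEPTABLE_THRESHOLDS["rmsea"]) \
        + int(not fit.heywood)
    return FitIndices(chi2=chi2, df=df, p_chi2=p, chi2_over_df=ratio,
                      cfi=cfi, rmsea=rmsea, bic=bic, n_good_indicators=good,
                      n_acceptable_indicators=acceptable,
                      rmsea_undefined=rmsea_undef)


def fit_all_variants(panel, variants=(1, 2, 3, 4, 5),
                     occasions=tuple(DEFAULT_SCHEDULE),
                     pgtol: float = 1e-8) -> list:
    """Fit every variant plus its matching baselines and attach fit indices."""
    y, X = _coerce_panel(panel)
    baselines = {}
    fits = []
    for v in variants:
        spec = build_lgc_spec(v, occasions=occasions)
        fit = fit_lgc(spec, (y, X), pgtol=pgtol)
        key = bool(spec.covariate_factors)
        if key not in baselines:
            baselines[key] = fit_baselines((y, X), with_covariates=key,
                                           pgtol=pgtol)
        sat, ind = baselines[key]
        if fit.converged and sat.converged and ind.converged:
            fit.fit = compute_fit_indices(fit, sat, ind)
        fits.append(fit)
    return fits


@dataclass
class SelectionResult:
    selected: LGCFit | None
    audit: pd.DataFrame

    @property
    def selected_variant(self) -> int:
        return self.selected.spec.variant_id


def select_model(fits) -> SelectionResult:
    """Rule-based selection among candidate fits.

    Non-converged fits and Heywood solutions are disqualified.  Among the
    rest the fit with the most good indicators wins; ties go to the smallest
    BIC.  The audit trail records every model's classification.
    """
    rows = []
    eligible = []
    for fit in fits:
        reason = ""
        if not fit.converged:
            reason = "did not converge"
        elif fit.heywood:
            reason = "Heywood case"
        elif fit.fit is None:
            reason = "fit indices unavailable"
        else:
            eligible.append(fit)
        rows.append({
            "variant": fit.spec.variant_id,
            "converged": fit.converged,
            "heywood": fit.heywood,
            "n_good_indicators": (fit.fit.n_good_indicators
                                  if fit.fit else np.nan),
            "bic": fit.fit.bic if fit.fit else np.nan,
            "eligible": not reason,
            "reason": reason,
        })
    audit = pd.DataFrame(rows)
    if not eligible:
        raise ValueError("all candidate models disqualified:\n"
                         + audit.to_string(index=False))
    best_good = max(f.fit.n_good_indicators for f in eligible)
    tied = [f for f in eligible if f.fit.n_good_indicators == best_good]
    selected = min(tied, key=lambda f: f.fit.bic)
    audit["selected"] = audit["variant"] == selected.spec.variant_id
    return SelectionResult(selected=selected, audit=audit)


NOT_COMPARABLE = "not comparable"


def ci_overlap(fit_a: LGCFit, fit_b: LGCFit, parameter_name: str):
    """Do the 95% CIs of a parameter overlap between two fits?

    Returns True/False for closed-interval overlap, or the string
    ``"not comparable"`` when the parameter is absent from either model
    (e.g. a quadratic slope compared against a linear model).
    """
    if parameter_name not in fit_a.ci95 or parameter_name not in fit_b.ci95:
        return NOT_COMPARABLE
    lo_a, hi_a = fit_a.ci95[parameter_name]
    lo_b, hi_b = fit_b.ci95[parameter_name]
    if any(math.isnan(v) for v in (lo_a, hi_a, lo_b, hi_b)):
        return NOT_COMPARABLE
    return max(lo_a, lo_b) <= min(hi_a, hi_b)
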