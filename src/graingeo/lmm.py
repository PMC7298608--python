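"""Likelihood-based estimation of the (multivariate) spatial linear mixed model.

The model for the stacked observations ``y`` (one row per variable/site
combination) is

    y = X beta + eta + eps

where ``eta`` are spatially correlated random effects with a shared Matérn
correlation and coregionalization matrix ``S``, and ``eps`` are nugget
effects with covariance ``T`` shared only between co-located rows.
Covariance parameters are estimated by ML or REML; the fixed effects follow
by generalized least squares at the optimum, and likelihood-ratio tests on
nested fixed-effect sets use ML fits.

Two fitting paths share one objective:

* single-variable stacks use an exact profile likelihood — for each
  candidate distance parameter the Matérn correlation matrix is
  eigendecomposed once, and the relative nugget share and the total
  variance are profiled analytically;
* multivariate stacks minimise the packed negative log-likelihood by
  multi-start Nelder–Mead followed by a quasi-Newton polish.  Variances are
  packed as logs and correlation matrices through Cholesky angles, which
  guarantees positive semi-definiteness throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import cdist
from scipy.special import expit, logit
from scipy.stats import chi2

from .covariance import (
    Coregionalization,
    CoregionalizationError,
    MaternCorrelation,
    build_joint_cov,
    cholesky_with_jitter,
    matern_corr,
)

__all__ = [
    "ObservationStack",
    "LMMFit",
    "CoregPacker",
    "build_stack",
    "univariate_stack",
    "negloglik",
    "fit_lmm",
    "lr_test",
    "profile_kappa",
    "adjusted_r2",
]

_SENTINEL = 1e10  # optimizer-safe value returned when a parameter vector is invalid
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class ObservationStack:
    """Stacked multivariate observations with a block-structured design matrix.

    ``var`` holds 0-based variable indices (0 = the target grain).  Each
    (variable, site) pair may appear at most once and design rows align 1:1
    with response rows.
    """

    var: np.ndarray
    site: np.ndarray
    coords: np.ndarray
    y: np.ndarray
    X: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.var = np.asarray(self.var, dtype=int)
        self.site = np.asarray(self.site)
        self.coords = np.asarray(self.coords, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if not (len(self.var) == len(self.site) == self.coords.shape[0] == self.X.shape[0] == n):
            raise ValueError("stack arrays must have matching first dimensions")
        if self.X.shape[1] != len(self.labels):
            raise ValueError("labels must match design matrix columns")
        pairs = list(zip(self.var.tolist(), self.site.tolist()))
        if len(set(pairs)) != n:
            raise ValueError("each (variable, site) pair may appear at most once")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise ValueError("stack contains missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_vars(self) -> int:
        return int(self.var.max()) + 1

    def subset(self, keep: np.ndarray) -> "ObservationStack":
        return ObservationStack(
            self.var[keep], self.site[keep], self.coords[keep], self.y[keep],
            self.X[keep], list(self.labels),
        )

    def with_columns(self, cols: np.ndarray, names: list[str]) -> "ObservationStack":
        """Append fixed-effect columns (aligned to rows)."""
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != self.n:
            cols = cols.T
        return ObservationStack(
            self.var, self.site, self.coords, self.y,
            np.column_stack([self.X, cols]), list(self.labels) + list(names),
        )


def univariate_stack(
    df: pd.DataFrame,
    response: str,
    predictors: list[str] = (),
    site_col: str = "site_id",
    x_col: str = "x_km",
    y_col: str = "y_km",
) -> ObservationStack:
    """Single-variable stack with an intercept and optional predictor columns."""
    n = len(df)
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in predictors])
    return ObservationStack(
        var=np.zeros(n, dtype=int),
        site=df[site_col].to_numpy(),
        coords=df[[x_col, y_col]].to_numpy(float),
        y=df[response].to_numpy(float),
        X=X,
        labels=["const"] + list(predictors),
    )


def build_stack(
    frames: list[pd.DataFrame],
    predictors: list[list[str]],
    response: str,
    var_names: list[str] | None = None,
    site_col: str = "site_id",
    x_col: str = "x_km",
    y_col: str = "y_km",
) -> ObservationStack:
    """Stack one data frame per variable with a block-diagonal design matrix.

    Variable ``v`` gets an intercept plus ``predictors[v]``; columns are
    labelled ``"<var>:<name>"`` so target-variable columns can be recovered
    for prediction.
    """
    if var_names is None:
        var_names = [f"y{v + 1}" for v in range(len(frames))]
    blocks, labels = [], []
    for v, (df, preds) in enumerate(zip(frames, predictors, strict=True)):
        labels += [f"{var_names[v]}:const"] + [f"{var_names[v]}:{c}" for c in preds]
    k = len(labels)
    var_l, site_l, coords_l, y_l, X_l = [], [], [], [], []
    col = 0
    for v, (df, preds) in enumerate(zip(frames, predictors, strict=True)):
        n = len(df)
        Xv = np.zeros((n, k))
        Xv[:, col] = 1.0
        for j, c in enumerate(preds):
            Xv[:, col + 1 + j] = df[c].to_numpy(float)
        col += 1 + len(preds)
        var_l.append(np.full(n, v))
        site_l.append(df[site_col].to_numpy())
        coords_l.append(df[[x_col, y_col]].to_numpy(float))
        y_l.append(df[response].to_numpy(float))
        X_l.append(Xv)
    return ObservationStack(
        np.concatenate(var_l), np.concatenate(site_l), np.vstack(coords_l),
        np.concatenate(y_l), np.vstack(X_l), labels,
    )


# ---------------------------------------------------------------------------
# correlation-matrix parameterization (Cholesky angles)
# ---------------------------------------------------------------------------


def _corr_from_angles(p: int, angles: np.ndarray, zero01: bool = False) -> np.ndarray:
    """Correlation matrix from hypersphere angles in (0, pi).

    Row ``i`` of the Cholesky factor is a unit vector parameterized by
    ``i`` angles.  With ``zero01`` the angle fixing entry (1, 0) is pinned
    at pi/2 so the (0, 1) correlation is exactly zero (structural zero for
    variable pairs never co-located).
    """
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    it = iter(np.asarray(angles, dtype=float))
    for i in range(1, p):
        prod = 1.0
        for j in range(i):
            theta = np.pi / 2.0 if (zero01 and i == 1 and j == 0) else next(it)
            L[i, j] = np.cos(theta) * prod
            prod *= np.sin(theta)
        L[i, i] = prod
    return L @ L.T


def _angles_from_corr(R: np.ndarray, zero01: bool = False) -> np.ndarray:
    p = R.shape[0]
    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    L /= np.linalg.norm(L, axis=1, keepdims=True)
    angles = []
    for i in range(1, p):
        prod = 1.0
        for j in range(i):
            c = np.clip(L[i, j] / prod, -1.0 + 1e-12, 1.0 - 1e-12)
            theta = np.arccos(c)
            if not (zero01 and i == 1 and j == 0):
                angles.append(theta)
            prod *= np.sin(theta)
    return np.asarray(angles)


class CoregPacker:
    """Bijection between a Coregionalization and an unconstrained vector.

    Layout: log nugget variances (p), nugget-correlation angles (masked
    pair excluded), log correlated variances (p), correlated-correlation
    angles, log phi.  Angles map to (0, pi) through a scaled logistic, so
    any real vector decodes to a valid (PSD) structure.  kappa is fixed,
    never estimated jointly.
    """

    def __init__(self, p: int, kappa: float, mask01: bool = False):
        if mask01 and p < 2:
            raise ValueError("mask requires at least two variables")
        self.p = p
        self.kappa = float(kappa)
        self.mask01 = bool(mask01)
        n_ang = p * (p - 1) // 2
        self.n_t_angles = n_ang - (1 if mask01 else 0)
        self.n_s_angles = n_ang
        self.n_params = 2 * p + self.n_t_angles + self.n_s_angles + 1

    def _mask_matrix(self) -> np.ndarray | None:
        if not self.mask01:
            return None
        mask = np.zeros((self.p, self.p), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        return mask

    def pack(self, coreg: Coregionalization) -> np.ndarray:
        p = self.p
        t_var = np.maximum(np.diag(coreg.T), 1e-12)
        s_var = np.maximum(np.diag(coreg.S), 1e-12)
        Rt = coreg.T / np.sqrt(np.outer(t_var, t_var))
        Rs = coreg.S / np.sqrt(np.outer(s_var, s_var))
        np.fill_diagonal(Rt, 1.0)
        np.fill_diagonal(Rs, 1.0)
        z_t = logit(_angles_from_corr(Rt, self.mask01) / np.pi) if p > 1 else np.empty(0)
        z_s = logit(_angles_from_corr(Rs) / np.pi) if p > 1 else np.empty(0)
        return np.concatenate(
            [np.log(t_var), z_t, np.log(s_var), z_s, [np.log(coreg.matern.phi)]]
        )

    def unpack(self, x: np.ndarray) -> Coregionalization:
        x = np.asarray(x, dtype=float)
        if len(x) != self.n_params:
            raise ValueError("packed vector has wrong length")
        p = self.p
        i = 0
        t_var = np.exp(x[i : i + p]); i += p
        z_t = x[i : i + self.n_t_angles]; i += self.n_t_angles
        s_var = np.exp(x[i : i + p]); i += p
        z_s = x[i : i + self.n_s_angles]; i += self.n_s_angles
        phi = float(np.exp(x[i]))
        Rt = _corr_from_angles(p, np.pi * expit(z_t), self.mask01)
        Rs = _corr_from_angles(p, np.pi * expit(z_s))
        T = Rt * np.sqrt(np.outer(t_var, t_var))
        S = Rs * np.sqrt(np.outer(s_var, s_var))
        mask = self._mask_matrix()
        if mask is not None:
            T = T.copy()
            T[mask] = 0.0
        return Coregionalization(
            T=T, S=S, matern=MaternCorrelation(self.kappa, phi), nugget_zero_mask=mask
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _gls(V_chol: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS pieces given the lower Cholesky factor of V."""
    Xw = linalg.solve_triangular(V_chol, X, lower=True)
    yw = linalg.solve_triangular(V_chol, y, lower=True)
    A = Xw.T @ Xw  # X' V^-1 X
    b = Xw.T @ yw
    beta = np.linalg.solve(A, b)
    resid_quad = float(yw @ yw - beta @ b)  # r' V^-1 r at the GLS optimum
    return beta, A, resid_quad


def _nll_from_pieces(n: int, k: int, logdetV: float, A: np.ndarray, quad: float, method: str):
    if method == "ML":
        return 0.5 * (n * _LOG2PI + logdetV + quad)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return _SENTINEL
    return 0.5 * ((n - k) * _LOG2PI + logdetV + logdetA + quad)


def _negloglik_core(
    x: np.ndarray,
    stack: ObservationStack,
    packer: CoregPacker,
    method: str,
    site_cache: dict | None,
    profile_scale: bool,
) -> tuple[float, float]:
    """(negative log-likelihood, profiled scale factor).

    With ``profile_scale`` the likelihood is maximised analytically over a
    common multiplier of T and S (the packing is scale-redundant, so this
    removes a flat direction from the numerical search).
    """
    try:
        coreg = packer.unpack(x)
    except (CoregionalizationError, ValueError, FloatingPointError):
        return _SENTINEL, 1.0
    try:
        V = _joint_cov_fast(stack, coreg, site_cache)
        L = cholesky_with_jitter(V)
    except np.linalg.LinAlgError:
        return _SENTINEL, 1.0
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    try:
        beta, A, quad = _gls(L, stack.X, stack.y)
    except np.linalg.LinAlgError:
        return _SENTINEL, 1.0
    n, k = stack.n, stack.X.shape[1]
    if not profile_scale:
        nll = _nll_from_pieces(n, k, logdetV, A, quad, method)
        return (nll if np.isfinite(nll) else _SENTINEL), 1.0
    if quad <= 0:
        return _SENTINEL, 1.0
    dof = n if method == "ML" else n - k
    c = quad / dof
    if method == "ML":
        nll = 0.5 * (n * _LOG2PI + logdetV + n * np.log(c) + n)
    else:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return _SENTINEL, 1.0
        nll = 0.5 * ((n - k) * _LOG2PI + logdetV + logdetA + (n - k) * np.log(c) + (n - k))
    return (nll if np.isfinite(nll) else _SENTINEL), c


def _negloglik_and_grad(
    x: np.ndarray,
    stack: ObservationStack,
    packer: CoregPacker,
    method: str,
    cache: dict,
) -> tuple[float, np.ndarray]:
    """Scale-profiled negative log-likelihood and its analytic gradient.

    Uses the standard identities d logdet = tr(W dV) (W = V^-1 for ML, the
    REML projection P for REML) and d(y'Py) = -(Py)' dV (Py).  Because
    dV/dtheta factorizes over variable pairs as dS[u,v]*rho + dT[u,v]*same,
    the trace terms collapse to p x p contractions of block sums, so a
    gradient costs only a few likelihood evaluations.
    """
    n_par = packer.n_params
    try:
        coreg = packer.unpack(x)
    except (CoregionalizationError, ValueError, FloatingPointError):
        return _SENTINEL, np.zeros(n_par)
    idx = cache["row_site"]
    u = stack.var
    rho = _matern_tabulated(cache["dist"], coreg.matern)[np.ix_(idx, idx)]
    same = cache["same"]
    V = coreg.S[np.ix_(u, u)] * rho + coreg.T[np.ix_(u, u)] * same
    try:
        L = cholesky_with_jitter(V)
        beta, A, quad = _gls(L, stack.X, stack.y)
    except np.linalg.LinAlgError:
        return _SENTINEL, np.zeros(n_par)
    if quad <= 0:
        return _SENTINEL, np.zeros(n_par)
    n, k = stack.n, stack.X.shape[1]
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    dof = n if method == "ML" else n - k
    c_scale = quad / dof
    if method == "ML":
        nll = 0.5 * (n * _LOG2PI + logdetV + n * np.log(c_scale) + n)
    else:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return _SENTINEL, np.zeros(n_par)
        nll = 0.5 * ((n - k) * _LOG2PI + logdetV + logdetA
                     + (n - k) * np.log(c_scale) + (n - k))
    if not np.isfinite(nll):
        return _SENTINEL, np.zeros(n_par)

    # weight matrix for the trace term and the projected residual q = P y
    eye = np.eye(stack.n)
    Vi = linalg.cho_solve((L, True), eye)
    ViX = linalg.cho_solve((L, True), stack.X)
    Ainv_XtVi = np.linalg.solve(A, ViX.T)
    q = Vi @ stack.y - ViX @ (Ainv_XtVi @ stack.y)
    W = Vi if method == "ML" else Vi - ViX @ Ainv_XtVi
    fac = dof / quad

    # block sums over variable pairs
    p = packer.p
    onehot = [(u == a) for a in range(p)]

    def block_sums(M):
        out = np.zeros((p, p))
        for a in range(p):
            Ma = M[onehot[a]]
            for b in range(p):
                out[a, b] = Ma[:, onehot[b]].sum()
        return out

    W_rho, W_same = W * rho, W * same
    qq = np.outer(q, q)
    Q_rho, Q_same = qq * rho, qq * same
    G_S, G_T = block_sums(W_rho), block_sums(W_same)
    H_S, H_T = block_sums(Q_rho), block_sums(Q_same)

    # phi direction: finite difference of the correlation surface in log phi
    eps = 1e-6
    m2 = MaternCorrelation(coreg.matern.kappa, coreg.matern.phi * (1.0 + eps))
    drho = (_matern_tabulated(cache["dist"], m2)[np.ix_(idx, idx)] - rho) / eps
    Suu = coreg.S[np.ix_(u, u)]
    tr_phi = float(np.sum(W * (Suu * drho)))
    q_phi = float(q @ (Suu * drho) @ q)

    grad = np.zeros(n_par)
    h = 1e-7
    for j in range(n_par - 1):  # finite-difference the small matrices only
        xj = x.copy()
        xj[j] += h
        cj = packer.unpack(xj)
        dT = (cj.T - coreg.T) / h
        dS = (cj.S - coreg.S) / h
        grad[j] = 0.5 * (np.sum(dS * G_S) + np.sum(dT * G_T)
                         - fac * (np.sum(dS * H_S) + np.sum(dT * H_T)))
    grad[-1] = 0.5 * (tr_phi - fac * q_phi)
    return nll, grad


def negloglik(
    x: np.ndarray,
    stack: ObservationStack,
    packer: CoregPacker,
    method: str = "ML",
    _site_cache: dict | None = None,
) -> float:
    """Negative log-likelihood of packed covariance parameters.

    Fixed effects are profiled out by GLS; REML adds the restricted
    determinant term for X.  Invalid parameter vectors and factorization
    failures return a large finite sentinel so optimizers can continue.
    """
    return _negloglik_core(x, stack, packer, method, _site_cache, False)[0]


def _site_geometry(stack: ObservationStack) -> dict:
    """Unique-site distance matrix and row->site index, reused across evals."""
    sites, idx = np.unique(stack.site, return_inverse=True)
    first = np.zeros(len(sites), dtype=int)
    first[idx[::-1]] = np.arange(stack.n - 1, -1, -1)
    site_coords = stack.coords[first]
    return {
        "row_site": idx,
        "dist": cdist(site_coords, site_coords),
        "same": idx[:, None] == idx[None, :],
    }


def _matern_tabulated(D: np.ndarray, m: MaternCorrelation, n_grid: int = 2000) -> np.ndarray:
    """Matérn correlation by linear interpolation on a log-spaced distance table.

    The correlation is smooth in distance, so a 2000-point table keeps the
    relative error below ~1e-7 — negligible against the likelihood's
    optimization tolerance — while avoiding a Bessel evaluation per pair.
    """
    pos = D[D > 0]
    if pos.size == 0:
        return np.ones_like(D)
    grid = np.geomspace(pos.min(), D.max(), n_grid)
    vals = matern_corr(grid, m)
    R = np.interp(D.ravel(), grid, vals).reshape(D.shape)
    R[D == 0] = 1.0
    return R


def _joint_cov_fast(stack: ObservationStack, coreg: Coregionalization, cache: dict | None):
    """build_joint_cov specialised to a stack, with Matérn evaluated once per site pair."""
    if cache is None:
        return build_joint_cov(stack.var, stack.coords, coreg, site_id=stack.site)
    rho_site = _matern_tabulated(cache["dist"], coreg.matern)
    idx = cache["row_site"]
    rho = rho_site[np.ix_(idx, idx)]
    u = stack.var
    return coreg.S[np.ix_(u, u)] * rho + coreg.T[np.ix_(u, u)] * cache["same"]


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """A fitted spatial linear mixed model."""

    labels: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    coreg: Coregionalization
    loglik: float
    method: str
    n_obs: int
    converged: bool = True
    starts: pd.DataFrame | None = field(default=None, repr=False)
    profile: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_se = np.asarray(self.beta_se, dtype=float)
        if np.any(self.beta_se < 0):
            raise ValueError("standard errors must be non-negative")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    @property
    def kappa(self) -> float:
        return self.coreg.matern.kappa

    @property
    def phi(self) -> float:
        return self.coreg.matern.phi

    def fixed_effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "estimate": self.beta, "std_error": self.beta_se}
        )

    def summary(self) -> str:
        """Plain-text report: coefficient table plus variance/correlation matrices."""
        lines = [f"Spatial LMM fit ({self.method}), n = {self.n_obs}, "
                 f"log-likelihood = {self.loglik:.3f}"]
        lines.append("\nFixed effects")
        for lab, b, se in zip(self.labels, self.beta, self.beta_se):
            lines.append(f"  {lab:<30s} {b:>12.4f}  (se {se:.4f})")
        lines.append("\nRandom effects parameters")
        lines.append(f"  kappa {self.kappa:.4g}   phi {self.phi:.4g} km")
        t_var = np.diag(self.coreg.T)
        s_var = np.diag(self.coreg.S)
        lines.append("  nugget variances     " + "  ".join(f"{v:.4f}" for v in t_var))
        lines.append("  correlated variances " + "  ".join(f"{v:.4f}" for v in s_var))

        def corr(M, v):
            with np.errstate(invalid="ignore", divide="ignore"):
                R = M / np.sqrt(np.outer(v, v))
            return np.nan_to_num(R, nan=0.0)

        for title, M, v in [("nugget", self.coreg.T, t_var), ("spatially correlated", self.coreg.S, s_var)]:
            lines.append(f"  {title} correlations")
            R = corr(M, v)
            for i in range(len(v)):
                lines.append("    " + "  ".join(f"{R[i, j]:6.2f}" for j in range(i + 1)))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single-variable exact profile fit
# ---------------------------------------------------------------------------

_spectral_cache: dict = {}


def _eig_matern(coords_key, D: np.ndarray, kappa: float, phi: float):
    key = (coords_key, round(kappa, 10), round(float(phi), 10))
    hit = _spectral_cache.get(key)
    if hit is not None:
        return hit
    R = matern_corr(D, MaternCorrelation(kappa, phi))
    lam, Q = linalg.eigh(R)
    lam = np.maximum(lam, 0.0)
    if D.shape[0] <= 1000:
        if len(_spectral_cache) > 200:
            _spectral_cache.clear()
        _spectral_cache[key] = (lam, Q)
    return lam, Q


def _profile_nll_w(lam, yt, Xt, w, method):
    d = np.maximum((1.0 - w) + w * lam, 1e-300)
    Xd = Xt / d[:, None]
    A = Xt.T @ Xd
    b = Xd.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return _SENTINEL, None
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / d))
    n, k = Xt.shape
    sumlogd = float(np.sum(np.log(d)))
    if rss <= 0:
        return _SENTINEL, None
    if method == "ML":
        s2 = rss / n
        nll = 0.5 * (n * _LOG2PI + n * np.log(s2) + sumlogd + n)
    else:
        s2 = rss / (n - k)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return _SENTINEL, None
        nll = 0.5 * ((n - k) * _LOG2PI + (n - k) * np.log(s2) + sumlogd + logdetA + (n - k))
    return nll, (beta, A, s2, w)


def _fit_univariate(
    stack: ObservationStack,
    method: str,
    kappa: float,
    phi_grid: np.ndarray | None = None,
    refine: bool = True,
) -> LMMFit:
    D = cdist(stack.coords, stack.coords)
    coords_key = hash(stack.coords.tobytes())
    dmax = float(D.max())
    if dmax == 0:
        raise ValueError("at least two distinct sites are required")
    if phi_grid is None:
        phi_grid = np.geomspace(dmax / 200.0, 2.0 * dmax, 18)
    y, X = stack.y, stack.X

    def profile_w_grid(lam, yt, Xt, w_grid):
        """Vectorized profile likelihood over a grid of spatial-share values."""
        d = (1.0 - w_grid)[:, None] + w_grid[:, None] * lam[None, :]
        d = np.maximum(d, 1e-300)
        inv_d = 1.0 / d
        A = np.einsum("wn,np,nq->wpq", inv_d, Xt, Xt)
        b = np.einsum("wn,np,n->wp", inv_d, Xt, yt)
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return np.full(len(w_grid), _SENTINEL)
        rss = inv_d @ (yt * yt) - np.einsum("wp,wp->w", beta, b)
        n_, k_ = Xt.shape
        sumlogd = np.sum(np.log(d), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if method == "ML":
                nll = 0.5 * (n_ * _LOG2PI + n_ * np.log(rss / n_) + sumlogd + n_)
            else:
                sign, logdetA = np.linalg.slogdet(A)
                nll = 0.5 * ((n_ - k_) * _LOG2PI + (n_ - k_) * np.log(rss / (n_ - k_))
                             + sumlogd + logdetA + (n_ - k_))
                nll = np.where(sign > 0, nll, _SENTINEL)
        return np.where(np.isfinite(nll) & (rss > 0), nll, _SENTINEL)

    w_coarse = np.concatenate([[1e-12], np.linspace(0.02, 1.0 - 1e-9, 25)])

    def eval_phi(phi):
        lam, Q = _eig_matern(coords_key, D, kappa, phi)
        yt = Q.T @ y
        Xt = Q.T @ X
        nll_c = profile_w_grid(lam, yt, Xt, w_coarse)
        i = int(np.argmin(nll_c))
        lo = w_coarse[max(i - 1, 0)]
        hi = w_coarse[min(i + 1, len(w_coarse) - 1)]
        w_fine = np.linspace(lo, hi, 24)
        nll_f = profile_w_grid(lam, yt, Xt, w_fine)
        j = int(np.argmin(nll_f))
        cands = np.concatenate([[w_coarse[i]], [w_fine[j]]])
        nlls = np.concatenate([[nll_c[i]], [nll_f[j]]])
        kbest = int(np.argmin(nlls))
        return float(nlls[kbest]), float(cands[kbest]), (lam, yt, Xt)

    rows = []
    best = None
    for phi in phi_grid:
        nll, w, parts = eval_phi(phi)
        rows.append({"phi": phi, "nll": nll, "w": w})
        if best is None or nll < best[0]:
            best = (nll, phi, w, parts)

    if refine and len(phi_grid) > 2:
        i = int(np.argmin([r["nll"] for r in rows]))
        lo = phi_grid[max(i - 1, 0)]
        hi = phi_grid[min(i + 1, len(phi_grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(lambda p: eval_phi(p)[0], bounds=(lo, hi),
                                           method="bounded", options={"xatol": 1e-4 * dmax})
            nll, w, parts = eval_phi(res.x)
            if nll < best[0]:
                best = (nll, float(res.x), w, parts)

    nll, phi, w, (lam, yt, Xt) = best
    _, payload = _profile_nll_w(lam, yt, Xt, w, method)
    beta, A, s2, w = payload
    tau2 = max((1.0 - w) * s2, 0.0)
    sigma2 = max(w * s2, 0.0)
    beta_cov = np.linalg.inv(A) * s2
    coreg = Coregionalization(
        T=[[tau2]], S=[[sigma2]], matern=MaternCorrelation(kappa, phi)
    )
    return LMMFit(
        labels=list(stack.labels), beta=beta, beta_se=np.sqrt(np.diag(beta_cov)),
        coreg=coreg, loglik=-nll, method=method, n_obs=stack.n,
        profile=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# multivariate multi-start fit
# ---------------------------------------------------------------------------


def _default_starts(stack: ObservationStack, packer: CoregPacker, n_starts: int) -> list[np.ndarray]:
    p = packer.p
    t_var, s_var, phis = np.ones(p), np.ones(p), []
    for u in range(p):
        keep = stack.var == u
        sub = ObservationStack(
            np.zeros(keep.sum(), dtype=int), stack.site[keep], stack.coords[keep],
            stack.y[keep], np.ones((keep.sum(), 1)), ["const"],
        )
        try:
            dmax = float(np.max(cdist(sub.coords, sub.coords)))
            m = _fit_univariate(sub, "ML", packer.kappa, refine=False,
                                phi_grid=np.geomspace(dmax / 100.0, dmax, 10))
            t_var[u] = max(m.coreg.T[0, 0], 1e-6)
            s_var[u] = max(m.coreg.S[0, 0], 1e-6)
            phis.append(m.phi)
        except Exception:
            v = np.var(sub.y) or 1.0
            t_var[u], s_var[u] = v / 2, v / 2
            phis.append(np.max(cdist(sub.coords, sub.coords)) / 4 or 1.0)
    phi0 = float(np.exp(np.mean(np.log(phis))))

    def make(corr, phi):
        z = logit(np.arccos(np.clip(corr, -0.99, 0.99)) / np.pi)
        return np.concatenate([
            np.log(t_var), np.full(packer.n_t_angles, z),
            np.log(s_var), np.full(packer.n_s_angles, z),
            [np.log(phi)],
        ])

    recipes = [(0.0, phi0), (0.4, phi0), (0.0, phi0 * 0.4), (0.4, phi0 * 2.5), (-0.3, phi0)]
    return [make(c, f) for c, f in recipes[:n_starts]]


def fit_lmm(
    stack: ObservationStack,
    method: str = "REML",
    kappa: float = 2.0,
    n_starts: int = 5,
    mask01: bool | None = None,
    phi_grid: np.ndarray | None = None,
    refine: bool = True,
    maxiter: int | None = None,
) -> LMMFit:
    """Fit the spatial LMM at fixed Matérn smoothness ``kappa``.

    ``mask01`` forces a structural zero nugget covariance between the first
    two variables (default: on whenever the stack holds >= 2 variables,
    matching the one-crop-per-site survey).
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if len(np.unique(stack.site)) < 2:
        raise ValueError("at least two distinct sites are required")
    p = stack.n_vars
    if p == 1:
        return _fit_univariate(stack, method, kappa, phi_grid=phi_grid, refine=refine)

    if mask01 is None:
        mask01 = True
    packer = CoregPacker(p, kappa, mask01=mask01)
    cache = _site_geometry(stack)
    obj = lambda x: _negloglik_core(x, stack, packer, method, cache, True)[0]
    grad_obj = lambda x: _negloglik_and_grad(x, stack, packer, method, cache)

    starts = _default_starts(stack, packer, n_starts)
    rows, best = [], None
    for i, x0 in enumerate(starts):
        res = optimize.minimize(grad_obj, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 400, "ftol": 1e-11})
        rows.append({"start": i, "nll": res.fun, "converged": bool(res.success)})
        if np.isfinite(res.fun) and res.fun < _SENTINEL and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {pd.DataFrame(rows)}")
    # derivative-free kick from the best point (escapes curved-ridge stalls),
    # then a final quasi-Newton descent
    kick = optimize.minimize(obj, best.x, method="Nelder-Mead",
                             options={"maxiter": maxiter or 100 * packer.n_params,
                                      "fatol": 1e-7, "xatol": 1e-5})
    if np.isfinite(kick.fun) and kick.fun < best.fun:
        best = kick
    polish = optimize.minimize(grad_obj, best.x, jac=True, method="L-BFGS-B",
                               options={"maxiter": 400, "ftol": 1e-11})
    if np.isfinite(polish.fun) and polish.fun < best.fun:
        best = polish

    # fold the profiled scale back into the variance parameters
    _, c_hat = _negloglik_core(best.x, stack, packer, method, cache, True)
    x_final = best.x.copy()
    x_final[: packer.p] += np.log(c_hat)
    s_lo = packer.p + packer.n_t_angles
    x_final[s_lo : s_lo + packer.p] += np.log(c_hat)
    coreg = packer.unpack(x_final)
    V = _joint_cov_fast(stack, coreg, cache)
    L = cholesky_with_jitter(V)
    beta, A, _ = _gls(L, stack.X, stack.y)
    beta_cov = np.linalg.inv(A)
    return LMMFit(
        labels=list(stack.labels), beta=beta, beta_se=np.sqrt(np.diag(beta_cov)),
        coreg=coreg, loglik=-float(best.fun), method=method, n_obs=stack.n,
        converged=any(r["converged"] for r in rows), starts=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


def lr_test(fit0: LMMFit, fit1: LMMFit) -> float:
    """Likelihood-ratio p-value for nested ML fits (chi-squared reference).

    The deviance 2*(l1 - l0) is clamped at zero (optimizer noise can leave
    the larger model fractionally below the smaller one).
    """
    if fit0.method != "ML" or fit1.method != "ML":
        raise ValueError("likelihood-ratio tests on fixed effects require ML fits")
    s0, s1 = set(fit0.labels), set(fit1.labels)
    if not s0 < s1:
        raise ValueError("fit0 must be strictly nested in fit1")
    df = len(s1) - len(s0)
    dev = 2.0 * (fit1.loglik - fit0.loglik)
    if dev < 0:
        if dev < -1e-6:
            warnings.warn(f"negative deviance {dev:.3g} clamped to 0", stacklevel=2)
        dev = 0.0
    return float(chi2.sf(dev, df))


def profile_kappa(
    stack: ObservationStack,
    kappa_grid=(0.25, 0.5, 1.0, 1.5, 2.0, 3.0),
    method: str = "ML",
    **fit_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Maximised log-likelihood over a grid of fixed Matérn smoothness values."""
    kappa_grid = list(kappa_grid)
    if not kappa_grid:
        raise ValueError("kappa grid must be non-empty")
    rows = []
    for k in kappa_grid:
        try:
            f = fit_lmm(stack, method=method, kappa=k, **fit_kwargs)
            rows.append({"kappa": k, "loglik": f.loglik, "ok": True})
        except Exception as exc:  # recorded, not fatal, unless every kappa fails
            rows.append({"kappa": k, "loglik": np.nan, "ok": False, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not table["ok"].any():
        raise RuntimeError("model fitting failed at every kappa in the grid")
    best = table.loc[table.loc[table["ok"], "loglik"].idxmax(), "kappa"]
    return float(best), table


def adjusted_r2(fit: LMMFit, stack: ObservationStack, target_var: int = 0) -> float:
    """Adjusted R^2 of the fixed-effects-only prediction of the target variable.

    1 - [RSS/(n-p)] / [TSS/(n-1)] on target-variable rows; constant-only
    models return 0 by convention.
    """
    rows = stack.var == target_var
    X0 = stack.X[rows]
    y0 = stack.y[rows]
    active = np.flatnonzero(np.any(X0 != 0.0, axis=0))
    p = len(active)
    n = len(y0)
    if p <= 1:
        return 0.0
    if n <= p:
        raise ValueError("adjusted R^2 undefined: n <= number of fixed-effect columns")
    resid = y0 - X0 @ fit.beta
    tss = float(np.sum((y0 - y0.mean()) ** 2))
    rss = float(np.sum(resid**2))
    return 1.0 - (rss / (n - p)) / (tss / (n - 1))
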