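"""E-BLUP cokriging and ordinary kriging with prediction error variances.

The E-BLUP at a target location x0 is the universal-cokriging form

    Z-hat(x0) = x0' beta-hat + c' V^{-1} (y - X beta-hat)

with c the covariance between the target-variable value at x0 and every
stacked observation.  The PEV is the full universal-kriging variance,
including the fixed-effect estimation term:

    PEV = sigma00 - c' V^{-1} c + u' (X' V^{-1} X)^{-1} u,   u = x0 - X' V^{-1} c

where sigma00 = T[0,0] + S[0,0] is the prior variance of a new
target-variable value (nugget included, since maps are interpreted at the
observation support).  Predictions are on the natural-log scale; exp of
the E-BLUP is the median-unbiased back-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import cdist

from .covariance import (
    MaternCorrelation,
    build_joint_cov,
    cholesky_with_jitter,
    matern_corr,
)
from .lmm import LMMFit, ObservationStack

__all__ = ["PredictionResult", "eblup_predict", "ok_predict", "back_transform_median"]


@dataclass
class PredictionResult:
    """Per-target E-BLUP (log scale), PEV and median back-transform."""

    x: np.ndarray
    y: np.ndarray
    pred_log: np.ndarray
    pev: np.ndarray
    tag: str = "E-BLUP"

    def __post_init__(self) -> None:
        self.pev = np.maximum(np.asarray(self.pev, dtype=float), 0.0)

    @property
    def median(self) -> np.ndarray:
        return back_transform_median(self.pred_log)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_km": self.x, "y_km": self.y, "pred_log": self.pred_log,
            "pev_log": self.pev, "median_mg_kg": self.median, "predictor": self.tag,
        })


def back_transform_median(log_predictions) -> np.ndarray:
    """Elementwise exp: the median-unbiased value under log-normal errors."""
    log_predictions = np.asarray(log_predictions, dtype=float)
    if not np.all(np.isfinite(log_predictions)):
        raise ValueError("log predictions must be finite")
    return np.exp(log_predictions)


def _target_design(fit: LMMFit, targets: pd.DataFrame, target_var: int, var_prefix: str | None):
    """Design rows for the target variable at the prediction locations.

    Columns belonging to other variables are zero.  For multivariate fits
    the target's columns are those labelled ``"<prefix>:<name>"``; the
    intercept is filled automatically and covariate columns are read from
    the target table.
    """
    k = len(fit.labels)
    m = len(targets)
    X0 = np.zeros((m, k))
    if var_prefix is None:  # univariate stack: plain labels
        own = list(fit.labels)
        strip = {lab: lab for lab in own}
    else:
        own = [lab for lab in fit.labels if lab.startswith(var_prefix + ":")]
        strip = {lab: lab.split(":", 1)[1] for lab in own}
    missing = [strip[lab] for lab in own
               if strip[lab] != "const" and strip[lab] not in targets.columns]
    if missing:
        raise ValueError(f"target covariate columns missing: {missing}")
    for lab in own:
        j = fit.labels.index(lab)
        name = strip[lab]
        X0[:, j] = 1.0 if name == "const" else targets[name].to_numpy(float)
    return X0


def eblup_predict(
    fit: LMMFit,
    stack: ObservationStack,
    targets: pd.DataFrame,
    target_var: int = 0,
    var_prefix: str | None = None,
    hull_warn: bool = True,
    chunk: int = 4000,
) -> PredictionResult:
    """E-BLUP with PEV at arbitrary targets from a fitted multivariate model.

    ``targets`` needs ``x_km``/``y_km`` plus a column for every fixed
    effect of the target variable.  All data enter every prediction (one
    Cholesky factorization reused across targets; targets are processed in
    blocks of ``chunk`` to bound memory on large grids).  Targets well
    outside the data's bounding box are flagged with a warning, not an
    error.
    """
    coreg = fit.coreg
    tx = targets["x_km"].to_numpy(float)
    ty = targets["y_km"].to_numpy(float)
    t_coords = np.column_stack([tx, ty])
    if var_prefix is None and stack.n_vars > 1:
        var_prefix = fit.labels[0].split(":", 1)[0] if ":" in fit.labels[0] else None
    X0 = _target_design(fit, targets, target_var, var_prefix)

    if hull_warn:
        lo, hi = stack.coords.min(0), stack.coords.max(0)
        margin = coreg.matern.phi
        outside = np.any((t_coords < lo - margin) | (t_coords > hi + margin), axis=1)
        if np.any(outside):
            warnings.warn(f"{int(outside.sum())} target(s) far outside the data hull",
                          stacklevel=2)

    V = build_joint_cov(stack.var, stack.coords, coreg, site_id=stack.site)
    L = cholesky_with_jitter(V)
    Xw = linalg.solve_triangular(L, stack.X, lower=True)
    yw = linalg.solve_triangular(L, stack.y, lower=True)
    A = Xw.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    sigma00 = coreg.T[target_var, target_var] + coreg.S[target_var, target_var]
    s_col = coreg.S[stack.var, target_var][:, None]

    m = len(tx)
    pred = np.empty(m)
    pev = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        # cross-covariance: targets are new locations (no shared nugget)
        rho = matern_corr(cdist(stack.coords, t_coords[lo:hi]), coreg.matern)
        cw = linalg.solve_triangular(L, s_col * rho, lower=True)
        pred[lo:hi] = X0[lo:hi] @ beta + cw.T @ resid_w
        u = X0[lo:hi].T - Xw.T @ cw  # k x block
        A_inv_u = np.linalg.solve(A, u)
        pev[lo:hi] = (sigma00 - np.einsum("ij,ij->j", cw, cw)
                      + np.einsum("ij,ij->j", u, A_inv_u))
    return PredictionResult(x=tx, y=ty, pred_log=pred, pev=pev, tag="E-BLUP")


def ok_predict(
    values: np.ndarray,
    coords: np.ndarray,
    nugget: float,
    sill: float,
    matern: MaternCorrelation,
    targets: np.ndarray,
) -> PredictionResult:
    """Ordinary kriging of a single variable (nugget + Matérn model).

    The local mean is estimated within the kriging system (weights sum to
    one); the PEV comes from the system's Lagrange form.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(values)
    if n < 3:
        raise ValueError("ordinary kriging requires at least 3 data")
    C = sill * matern_corr(cdist(coords, coords), matern) + nugget * np.eye(n)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    c = sill * matern_corr(cdist(coords, targets), matern)
    m = targets.shape[0]
    B = np.vstack([c, np.ones((1, m))])
    for attempt in range(2):
        try:
            sol = linalg.solve(A, B)
            break
        except linalg.LinAlgError:
            if attempt:
                raise
            A[:n, :n] += 1e-10 * max(sill + nugget, 1.0) * np.eye(n)
    lam, mu = sol[:n, :], sol[n, :]
    pred = lam.T @ values
    pev = (nugget + sill) - np.einsum("ij,ij->j", lam, c) - mu
    return PredictionResult(x=targets[:, 0], y=targets[:, 1], pred_log=pred,
                            pev=pev, tag="OK")


def ok_weights(values, coords, nugget, sill, matern, target):
    """Kriging weights and Lagrange multiplier for a single target (diagnostics)."""
    res_n = len(values)
    C = sill * matern_corr(cdist(coords, coords), matern) + nugget * np.eye(res_n)
    A = np.zeros((res_n + 1, res_n + 1))
    A[:res_n, :res_n] = C
    A[:res_n, res_n] = 1.0
    A[res_n, :res_n] = 1.0
    b = np.append(sill * matern_corr(cdist(coords, np.atleast_2d(target)), matern)[:, 0], 1.0)
    sol = linalg.solve(A, b)
    return sol[:res_n], sol[res_n]
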