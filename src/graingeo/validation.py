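"""Leave-one-out cross-validation with standardized squared prediction errors.

For every target-variable site the grain measurement (and, for the
multivariate E-BLUP, the soil-predicted value at the same site) is deleted
and re-predicted from the remaining data with the covariance and
fixed-effect parameters held fixed.  With valid PEVs the standardized
squared prediction error theta = (error)^2 / PEV has mean 1 and median
equal to the chi-squared(1) median, 0.4549; the observed median is compared
with a Monte-Carlo confidence interval for the median of n chi-squared(1)
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LMMFit, ObservationStack
from .prediction import ok_predict

__all__ = ["CrossValReport", "loocv", "median_sspe_interval"]

CHI2_1_MEDIAN = 0.454936  # median of the chi-squared distribution with 1 df


@dataclass
class CrossValReport:
    """Per-site LOOCV errors plus SSPE summaries."""

    table: pd.DataFrame  # site_id, observed, predicted, pev, error, sspe
    tag: str
    interval: tuple[float, float] | None = None

    @property
    def mean_sspe(self) -> float:
        t = self.table[self.table["pev"] > 0]
        return float(t["sspe"].mean())

    @property
    def median_sspe(self) -> float:
        t = self.table[self.table["pev"] > 0]
        return float(t["sspe"].median())

    @property
    def mean_pev(self) -> float:
        return float(self.table["pev"].mean())

    def summary(self) -> dict:
        return {
            "predictor": self.tag,
            "n": int(len(self.table)),
            "mean_sspe": self.mean_sspe,
            "median_sspe": self.median_sspe,
            "interval_low": self.interval[0] if self.interval else np.nan,
            "interval_high": self.interval[1] if self.interval else np.nan,
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def median_sspe_interval(
    n: int, nsim: int = 10000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo confidence interval for the median of n chi-squared(1) draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if nsim < 1000:
        raise ValueError("nsim must be >= 1000")
    rng = np.random.default_rng(seed)
    medians = np.median(rng.chisquare(1.0, size=(nsim, n)), axis=1)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [a, 1.0 - a])
    return float(lo), float(hi)


def loocv(
    stack: ObservationStack,
    fit: LMMFit,
    predictor: str = "EBLUP",
    target_var: int = 0,
    soil_pred_var: int = 2,
    interval_seed: int = 0,
    interval_nsim: int = 4000,
) -> CrossValReport:
    """Leave-one-out cross-validation of the E-BLUP or of ordinary kriging.

    Parameters are *not* re-estimated per deletion.  For ``"EBLUP"`` both
    the target-grain row and the soil-predicted row at the deleted site are
    removed; ``"OK"`` uses the target-variable data only, with the marginal
    (nugget + Matérn) model of the fit.  Sites whose removal would leave
    fewer than 3 data are skipped with a log entry in the report.
    """
    if predictor not in ("EBLUP", "OK"):
        raise ValueError("predictor must be 'EBLUP' or 'OK'")
    t_rows = np.flatnonzero(stack.var == target_var)
    if len(t_rows) < 10:
        raise ValueError("at least 10 target-variable sites are required")
    rows = []
    if predictor == "OK":
        vals = stack.y[t_rows]
        coords = stack.coords[t_rows]
        tau2 = fit.coreg.T[target_var, target_var]
        sigma2 = fit.coreg.S[target_var, target_var]
        for i, r in enumerate(t_rows):
            keep = np.ones(len(t_rows), dtype=bool)
            keep[i] = False
            if keep.sum() < 3:
                continue
            res = ok_predict(vals[keep], coords[keep], tau2, sigma2,
                             fit.coreg.matern, coords[i : i + 1])
            rows.append(_cv_row(stack.site[r], vals[i], res.pred_log[0], res.pev[0]))
    else:
        from scipy import linalg

        from graingeo.covariance import build_joint_cov, cholesky_with_jitter

        drop_vars = {target_var, soil_pred_var}
        # assemble the full covariance once; every deletion is a submatrix.
        # After removing the grain and soil-predicted rows at a site, no
        # remaining row shares that site, so the cross-covariance to the
        # deleted observation is exactly the corresponding column of V.
        V = build_joint_cov(stack.var, stack.coords, fit.coreg, site_id=stack.site)
        sigma00 = (fit.coreg.T[target_var, target_var]
                   + fit.coreg.S[target_var, target_var])
        for r in t_rows:
            site = stack.site[r]
            keep = np.flatnonzero(
                ~((stack.site == site) & np.isin(stack.var, list(drop_vars))))
            if len(keep) < 3:
                continue
            V_sub = V[np.ix_(keep, keep)]
            c = V[keep, r] - fit.coreg.T[stack.var[keep], target_var] * (
                stack.site[keep] == site)  # spatial part only (defensive; zero anyway)
            L = cholesky_with_jitter(V_sub)
            Xs, ys = stack.X[keep], stack.y[keep]
            Xw = linalg.solve_triangular(L, Xs, lower=True)
            yw = linalg.solve_triangular(L, ys, lower=True)
            cw = linalg.solve_triangular(L, c, lower=True)
            A = Xw.T @ Xw
            beta = np.linalg.solve(A, Xw.T @ yw)
            pred = float(stack.X[r] @ beta + cw @ (yw - Xw @ beta))
            u = stack.X[r] - Xw.T @ cw
            pev = float(sigma00 - cw @ cw + u @ np.linalg.solve(A, u))
            rows.append(_cv_row(site, stack.y[r], pred, max(pev, 0.0)))
    table = pd.DataFrame(rows)
    n_eff = int((table["pev"] > 0).sum())
    interval = median_sspe_interval(max(n_eff, 1), nsim=interval_nsim,
                                    seed=interval_seed) if n_eff else None
    return CrossValReport(table=table, tag="E-BLUP" if predictor == "EBLUP" else "OK",
                          interval=interval)


def _cv_row(site, observed, predicted, pev):
    err = observed - predicted
    return {
        "site_id": site, "observed": observed, "predicted": predicted,
        "pev": pev, "error": err,
        "sspe": err**2 / pev if pev > 0 else np.nan,
    }
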