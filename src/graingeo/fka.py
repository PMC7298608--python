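"""Factorial kriging analysis: scale decomposition of covariate surfaces.

A covariate's variogram is modelled as a nugget plus nested authorized
structures (short range before long range).  Ordinary kriging with the full
model then splits the surface into additive components — nugget, one per
structure, and the (locally estimated) mean — whose sum equals the ordinary
kriging estimate exactly.  Components can finally be screened as fixed
effects in the spatial LMM: a component is retained only if its
standardized coefficient falls outside [-2, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

from .covariance import EmpiricalVariogram, MaternCorrelation, matern_corr
from .lmm import LMMFit, ObservationStack, fit_lmm

__all__ = [
    "VariogramStructure",
    "NestedVariogramModel",
    "fit_nested_variogram",
    "krige_component",
    "filter_components",
]


def _structure_corr(h: np.ndarray, family: str, a: float, kappa: float = 1.5) -> np.ndarray:
    """Correlation (1 - unit semivariance) of one authorized structure."""
    h = np.asarray(h, dtype=float)
    if family == "exponential":
        return np.exp(-h / a)
    if family == "spherical":
        u = np.minimum(h / a, 1.0)
        return 1.0 - (1.5 * u - 0.5 * u**3)
    if family == "matern":
        return matern_corr(h, MaternCorrelation(kappa, a))
    raise ValueError(f"unknown variogram family {family!r}")


@dataclass(frozen=True)
class VariogramStructure:
    sill: float
    family: str
    a: float  # distance parameter, km
    kappa: float = 1.5

    def correlation(self, h) -> np.ndarray:
        return _structure_corr(h, self.family, self.a, self.kappa)


@dataclass
class NestedVariogramModel:
    """Nugget + nested structures, ranges strictly increasing (short first)."""

    nugget: float
    structures: list[VariogramStructure]
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nugget < 0 or any(s.sill < 0 for s in self.structures):
            raise ValueError("variances must be non-negative")
        ranges = [s.a for s in self.structures]
        if any(b <= a for a, b in zip(ranges, ranges[1:])):
            raise ValueError("structure ranges must be strictly increasing")

    @property
    def total_sill(self) -> float:
        return self.nugget + sum(s.sill for s in self.structures)

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = np.where(h > 0, self.nugget, 0.0)
        for s in self.structures:
            g = g + s.sill * (1.0 - s.correlation(h))
        return g

    def covariance(self, h, component: str | int = "all") -> np.ndarray:
        """Covariance of the full process or of one additive component."""
        h = np.asarray(h, dtype=float)
        if component == "all":
            c = self.nugget * (h == 0)
            for s in self.structures:
                c = c + s.sill * s.correlation(h)
            return c
        if component == "nugget":
            return self.nugget * (h == 0).astype(float)
        s = self.structures[int(component)]
        return s.sill * s.correlation(h)


def fit_nested_variogram(
    ev: EmpiricalVariogram,
    n_structures: int = 2,
    families: tuple[str, ...] = ("exponential", "exponential"),
) -> NestedVariogramModel:
    """Weighted-least-squares fit of a nested model to an empirical variogram.

    Weights are Cressie's N(h)/gamma_model(h)^2, so well-populated short
    lags dominate.  A flat empirical variogram collapses to a pure-nugget
    model with a warning.
    """
    ev = ev.populated()
    if len(ev.lags) < 5:
        raise ValueError("at least 5 populated bins are required")
    lags, gam, npairs = ev.lags, ev.gamma, ev.npairs.astype(float)
    gmean = float(np.mean(gam))
    if gmean <= 0 or np.ptp(gam) < 1e-12 * max(gmean, 1.0):
        warnings.warn("flat empirical variogram; returning a pure-nugget model",
                      stacklevel=2)
        return NestedVariogramModel(nugget=gmean, structures=[
            VariogramStructure(0.0, families[k], lags.max() * (k + 1))
            for k in range(n_structures)
        ], fit_info={"degenerate": True})

    hmax = float(lags.max())

    def unpack(x):
        c0 = x[0] ** 2
        sills = x[1 : 1 + n_structures] ** 2
        # ranges beyond ~2x the largest lag are unobservable; cap them
        a1 = min(abs(x[1 + n_structures]) + 1e-6, 2.0 * hmax)
        ranges = [a1]
        for k in range(1, n_structures):
            ranges.append(min(ranges[-1] + abs(x[1 + n_structures + k]) + 1e-6,
                              2.0 * hmax * (k + 1)))
        return c0, sills, ranges

    def model_gamma(x):
        c0, sills, ranges = unpack(x)
        g = np.full_like(lags, c0)
        for k in range(n_structures):
            g += sills[k] * (1.0 - _structure_corr(lags, families[k], ranges[k]))
        return g

    def objective(x):
        g = model_gamma(x)
        w = npairs / np.maximum(g, 1e-10) ** 2
        return float(np.sum(w * (gam - g) ** 2))

    best = None
    sill0 = np.sqrt(gmean / max(n_structures, 1))
    for a1_frac, a2_frac in [(0.1, 0.5), (0.05, 1.0), (0.3, 1.5)]:
        x0 = np.concatenate([
            [np.sqrt(0.2 * gmean)], np.full(n_structures, sill0),
            [a1_frac * hmax] + [max(a2_frac - a1_frac, 0.05) * hmax] * (n_structures - 1),
        ])
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    c0, sills, ranges = unpack(best.x)
    # a structure decorrelating below the first observable lag is
    # indistinguishable from nugget: fold it in
    h_min = float(lags.min())
    sills = list(sills)
    for k in range(n_structures):
        if ranges[k] < 0.5 * h_min and sills[k] > 0:
            c0 += sills[k]
            sills[k] = 0.0
    ranges = [max(a, 0.5 * h_min * (k + 1)) for k, a in enumerate(ranges)]
    for k in range(1, n_structures):  # keep ranges strictly increasing
        if ranges[k] <= ranges[k - 1]:
            ranges[k] = ranges[k - 1] * 1.001
    return NestedVariogramModel(
        nugget=c0,
        structures=[VariogramStructure(sills[k], families[k], ranges[k])
                    for k in range(n_structures)],
        fit_info={"method": "wls-cressie", "objective": best.fun,
                  "converged": bool(best.success)},
    )


def krige_component(
    values: np.ndarray,
    coords: np.ndarray,
    model: NestedVariogramModel,
    component: str | int,
    targets: np.ndarray,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Kriged surface of one additive component at the target locations.

    The kriging system uses the full nested model on the left side.  The
    right side carries the chosen component's covariance with unbiasedness
    constraint 0 (components have zero mean), or constraint 1 with zero
    spatial covariance for ``component="mean"``.  Summing nugget, all
    structure components and the mean reproduces the ordinary-kriging
    estimate exactly.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(values)
    D = cdist(coords, coords)
    C = model.covariance(D, "all")
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    d_t = cdist(coords, targets)
    m = targets.shape[0]
    B = np.zeros((n + 1, m))
    if component == "mean":
        B[n, :] = 1.0
    elif component == "all":
        B[:n, :] = model.covariance(d_t, "all")
        B[n, :] = 1.0
    else:
        B[:n, :] = model.covariance(d_t, component)
    for attempt in range(2):
        try:
            lam = linalg.solve(A, B)
            break
        except linalg.LinAlgError:
            if attempt:
                raise
            A[:n, :n] += jitter * max(model.total_sill, 1.0) * np.eye(n)
    return lam[:n, :].T @ values


def filter_components(
    stack: ObservationStack,
    candidates: pd.DataFrame,
    kappa: float = 0.5,
    threshold: float = 2.0,
    method: str = "ML",
    **fit_kwargs,
) -> tuple[list[str], LMMFit]:
    """Screen scale components by their standardized coefficients in the LMM.

    Fits the model with every candidate column included, retains those with
    |estimate / standard error| > ``threshold``, and refits with the
    retained set.  An empty candidate list returns the base fit unchanged.
    """
    names = list(candidates.columns)
    if not names:
        return [], fit_lmm(stack, method=method, kappa=kappa, **fit_kwargs)
    full = stack.with_columns(candidates.to_numpy(float), names)
    fit_all = fit_lmm(full, method=method, kappa=kappa, **fit_kwargs)
    retained = []
    for name in names:
        i = fit_all.labels.index(name)
        se = fit_all.beta_se[i]
        if se > 0 and abs(fit_all.beta[i] / se) > threshold:
            retained.append(name)
    if retained == names:
        return retained, fit_all
    refit_stack = stack.with_columns(candidates[retained].to_numpy(float), retained) \
        if retained else stack
    return retained, fit_lmm(refit_stack, method=method, kappa=kappa, **fit_kwargs)
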