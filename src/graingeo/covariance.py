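"""Matérn correlation, the linear model of coregionalization, and variograms.

The random part of the spatial model is a linear model of coregionalization
(LMC) for ``p`` jointly varying variables: a nugget covariance matrix ``T``
(spatially uncorrelated, but possibly cross-correlated, effects) plus a
spatially correlated covariance matrix ``S`` whose entries are scaled by a
single shared Matérn correlation function.  The covariance between a row
``(u, i)`` (variable u at site i) and ``(v, j)`` is::

    C[(u, i), (v, j)] = T[u, v] * 1{i == j} + S[u, v] * rho(||x_i - x_j||)

where ``rho`` is the Matérn correlation with smoothness ``kappa`` and
distance parameter ``phi`` (km).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, kv

__all__ = [
    "MaternCorrelation",
    "Coregionalization",
    "EmpiricalVariogram",
    "matern_corr",
    "build_joint_cov",
    "empirical_variogram",
]

PSD_TOL = -1e-10
CHOL_JITTER = 1e-10
_H_GUARD = 1e-10  # below h/phi = 1e-10 the Bessel evaluation underflows; return 1


class CoregionalizationError(ValueError):
    """Raised when a coregionalization structure is invalid."""


@dataclass(frozen=True)
class MaternCorrelation:
    """Matérn correlation function rho(h) = 2^(1-k)/Gamma(k) (h/phi)^k K_k(h/phi).

    ``kappa`` is the (dimensionless) smoothness, ``phi`` the distance
    parameter in km.  Distance is scaled as h/phi with no sqrt(2*kappa)
    factor, so fitted phi values are comparable across kappa only
    qualitatively.
    """

    kappa: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise CoregionalizationError("kappa must be > 0")
        if not (self.phi > 0):
            raise CoregionalizationError("phi must be > 0")

    def __call__(self, h) -> np.ndarray:
        return matern_corr(h, self)


def matern_corr(h, m: MaternCorrelation) -> np.ndarray:
    """Matérn correlation at distance(s) ``h`` (km, >= 0); rho(0) = 1 exactly."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    u = h / m.phi
    out = np.ones_like(u)
    mask = u >= _H_GUARD
    if np.any(mask):
        um = u[mask]
        k = m.kappa
        log_const = (1.0 - k) * np.log(2.0) - gammaln(k)
        with np.errstate(over="ignore", invalid="ignore"):
            val = np.exp(log_const + k * np.log(um)) * kv(k, um)
        out[mask] = np.clip(np.nan_to_num(val, nan=0.0), 0.0, 1.0)
    return out if out.ndim else float(out)


def _check_sym_psd(mat: np.ndarray, label: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise CoregionalizationError(f"{label} must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise CoregionalizationError(f"{label} must be symmetric")
    if np.any(np.diag(mat) < 0):
        raise CoregionalizationError(f"{label} diagonal must be non-negative")
    if np.min(np.linalg.eigvalsh(mat)) < PSD_TOL:
        raise CoregionalizationError(f"{label} is not positive semi-definite")


@dataclass
class Coregionalization:
    """Nugget matrix T, spatially correlated matrix S, and a shared Matérn.

    ``nugget_zero_mask`` marks variable pairs that are never co-located
    (e.g. the two crops, one observed per site); those entries of T are
    structural zeros.
    """

    T: np.ndarray
    S: np.ndarray
    matern: MaternCorrelation
    nugget_zero_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.validate()

    @property
    def p(self) -> int:
        return self.T.shape[0]

    def validate(self) -> None:
        _check_sym_psd(self.T, "nugget covariance T")
        _check_sym_psd(self.S, "correlated covariance S")
        if self.T.shape != self.S.shape:
            raise CoregionalizationError("T and S must have matching shape")
        if self.nugget_zero_mask is not None:
            mask = np.asarray(self.nugget_zero_mask, dtype=bool)
            if mask.shape != self.T.shape:
                raise CoregionalizationError("mask shape must match T")
            if np.any(self.T[mask] != 0.0):
                raise CoregionalizationError("masked nugget entries must be exactly 0")

    def sill(self) -> np.ndarray:
        """Per-variable prior variance T[u,u] + S[u,u]."""
        return np.diag(self.T) + np.diag(self.S)

    def marginal(self, u: int) -> "Coregionalization":
        """Single-variable coregionalization of variable ``u``."""
        return Coregionalization(
            T=self.T[u : u + 1, u : u + 1],
            S=self.S[u : u + 1, u : u + 1],
            matern=self.matern,
        )


def build_joint_cov(
    var_idx: np.ndarray,
    coords: np.ndarray,
    coreg: Coregionalization,
    site_id: np.ndarray | None = None,
    coords2: np.ndarray | None = None,
    var_idx2: np.ndarray | None = None,
    site_id2: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the joint covariance matrix of a stack of (variable, site) rows.

    With only the first three arguments the full symmetric n x n matrix is
    returned.  Supplying ``coords2``/``var_idx2`` gives the n x m
    cross-covariance between two row sets (the kriging right-hand side); in
    that case nugget terms contribute only where site ids match on both
    sides (never, if either side has no site ids).
    """
    coreg.validate()
    var_idx = np.asarray(var_idx, dtype=int)
    coords = np.asarray(coords, dtype=float)
    cross = coords2 is not None
    if not cross:
        coords2, var_idx2, site_id2 = coords, var_idx, site_id
    var_idx2 = np.asarray(var_idx2, dtype=int)
    coords2 = np.asarray(coords2, dtype=float)

    d = cdist(coords, coords2)
    rho = matern_corr(d, coreg.matern)
    cov = coreg.S[np.ix_(var_idx, var_idx2)] * rho

    if not cross:
        if site_id is None:
            same = d == 0.0
        else:
            site_id = np.asarray(site_id)
            same = site_id[:, None] == site_id[None, :]
        cov = cov + coreg.T[np.ix_(var_idx, var_idx2)] * same
    elif site_id is not None and site_id2 is not None:
        same = np.asarray(site_id)[:, None] == np.asarray(site_id2)[None, :]
        cov = cov + coreg.T[np.ix_(var_idx, var_idx2)] * same
    return cov


@dataclass
class EmpiricalVariogram:
    """Matheron estimator of the semivariance per lag bin.

    Empty bins are reported with ``npairs = 0`` and ``gamma = nan`` rather
    than dropped.
    """

    lags: np.ndarray
    gamma: np.ndarray
    npairs: np.ndarray
    bin_edges: np.ndarray = field(default=None, repr=False)

    def populated(self) -> "EmpiricalVariogram":
        keep = self.npairs > 0
        return EmpiricalVariogram(
            self.lags[keep], self.gamma[keep], self.npairs[keep], self.bin_edges
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag": self.lags, "gamma": self.gamma, "npairs": self.npairs})


def empirical_variogram(
    values: np.ndarray,
    coords: np.ndarray,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 15,
) -> EmpiricalVariogram:
    """Matheron semivariance gamma(h) = (1/2N(h)) sum (z_i - z_j)^2 per lag bin.

    Bins are left-closed, right-open.  Default binning: ``n_bins`` equal
    bins up to half the maximum pairwise distance.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("at least two points are required")
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(*(coords[iu] - coords[ju]).T)
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    if bin_edges is None:
        bin_edges = np.linspace(0.0, d.max() / 2.0, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.searchsorted(bin_edges, d, side="right") - 1
    valid = (idx >= 0) & (idx < len(bin_edges) - 1)
    nb = len(bin_edges) - 1
    npairs = np.bincount(idx[valid], minlength=nb)
    sums = np.bincount(idx[valid], weights=sq[valid], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(npairs > 0, sums / np.maximum(npairs, 1), np.nan)
    lags = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    if np.any(npairs == 0):
        warnings.warn("empty variogram bins reported with npairs=0", stacklevel=2)
    return EmpiricalVariogram(lags=lags, gamma=gamma, npairs=npairs, bin_edges=bin_edges)


def cholesky_with_jitter(mat: np.ndarray, jitter: float = CHOL_JITTER, tries: int = 4):
    """Lower Cholesky factor, adding an escalating diagonal jitter on failure."""
    scale = np.mean(np.diag(mat)) or 1.0
    eps = 0.0
    for _ in range(tries):
        try:
            return np.linalg.cholesky(mat + eps * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            eps = jitter * scale if eps == 0.0 else eps * 100.0
    raise np.linalg.LinAlgError("covariance matrix could not be factorized")
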