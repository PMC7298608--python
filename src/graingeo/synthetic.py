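"""Synthetic soil–crop surveys with the statistical structure the analysis assumes.

The generator emulates a regional grain-micronutrient survey: a spatially
spread primary sample on a fine grid (default 475 sites) plus a small set
of close pairs 100–1000 m away (default 25) to inform short-range variogram
estimation; one cereal crop observed per site; right-skewed soil properties
(some of which truly drive grain Se and some of which do not); exhaustive
covariate grids with nested short- and long-range spatial components, a
subset of which load on the same long-range latent field that drives the
grain.  Grain Se for each crop is log-linear in the true soil predictors
and the shared latent field, plus crop-specific spatially correlated and
nugget effects (correlated between crops in the spatial part only — the two
crops are never co-located, so their nugget covariance is a structural
zero).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import Coregionalization, MaternCorrelation, matern_corr
from .rasters import Grid, write_esri_ascii, write_manifest

__all__ = [
    "SurveyConfig",
    "SyntheticSurvey",
    "SOIL_PROPERTIES",
    "COVARIATE_NAMES",
    "draw_design",
    "plot_layout",
    "simulate_fields",
    "gaussian_field_grid",
    "assemble_survey",
    "write_survey",
]

SOIL_PROPERTIES = [
    "se_nit", "se_pho", "se_tmah", "ph", "total_oxides", "s_nit",
    "s_tmah", "i_pho", "soc", "oxalate_p", "pbi",
]

COVARIATE_NAMES = [
    "precipitation", "temperature", "slope", "topographic_index",
    "evi", "modis_b7", "modis_b1", "modis_b2", "modis_b4",
]

# (location, scale, lognormal?) on the generating scale.  Lognormal soils
# reproduce the heavy right skew of trace-element fractions; the others are
# near-symmetric so the skewness>1 transform rule has true negatives.
_SOIL_PARAMS: dict[str, tuple[float, float, bool]] = {
    "se_nit": (0.77, 0.55, True),
    "se_pho": (1.61, 0.44, True),
    "se_tmah": (5.43, 0.20, True),   # mildly skewed only: stays untransformed
    "ph": (6.74, 0.92, False),
    "total_oxides": (13470.0, 5620.0, False),
    "s_nit": (37.9, 11.0, False),
    "s_tmah": (1.56, 0.63, True),
    "i_pho": (4.94, 0.75, True),
    "soc": (1.46, 0.50, False),
    "oxalate_p": (5.85, 0.80, True),
    "pbi": (3.66, 0.59, True),
}

# spatial loading of each soil property on the shared long-range latent field
_SOIL_LATENT_LOADING: dict[str, float] = {
    "se_nit": 0.35, "se_pho": 0.30, "se_tmah": 0.15, "ph": 0.45,
    "total_oxides": 0.2, "s_nit": 0.1, "s_tmah": 0.1, "i_pho": 0.25,
    "soc": 0.0, "oxalate_p": 0.0, "pbi": 0.0,
}

# covariate generation: mean, sd, share of variance from the shared latent
# long-range field ("signal" covariates), share from an unrelated long-range
# field, share from a covariate-specific short-range field; remainder nugget
_COVARIATE_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    #              mean     sd    latent  other-long  short
    "precipitation": (1100.0, 180.0, 0.55, 0.00, 0.30),
    "temperature": (190.0, 25.0, 0.45, 0.10, 0.30),
    "slope": (5.0, 3.0, 0.30, 0.10, 0.45),
    "topographic_index": (8.0, 2.0, 0.00, 0.30, 0.50),
    "evi": (0.35, 0.10, 0.00, 0.45, 0.40),
    "modis_b7": (0.22, 0.05, 0.00, 0.40, 0.45),
    "modis_b1": (0.12, 0.04, 0.00, 0.40, 0.45),
    "modis_b2": (0.30, 0.06, 0.00, 0.40, 0.45),
    "modis_b4": (0.10, 0.03, 0.00, 0.40, 0.45),
}


@dataclass
class SurveyConfig:
    """Study conditions of one synthetic survey.

    Distances in km unless noted.  The true coefficients act on the
    *transformed* scale of each soil property (log for the lognormal ones),
    centred at the generating mean, so the intercept is the regional mean
    log concentration.
    """

    frame_km: tuple[float, float] = (300.0, 300.0)
    grid_spacing_km: float = 0.5
    n_primary: int = 475
    n_close_pairs: int = 25
    close_pair_bounds_m: tuple[float, float] = (100.0, 1000.0)
    teff_fraction: float = 0.5
    # grain random structure (teff, wheat)
    kappa: float = 2.0
    phi_km: float = 15.0
    nugget_vars: tuple[float, float] = (0.30, 0.35)
    correlated_vars: tuple[float, float] = (0.39, 0.54)
    grain_cross_corr: float = 0.6
    # latent / covariate geometry
    covariate_cell_km: float = 1.0
    long_range_km: float = 30.0
    short_range_km: float = 2.0
    latent_effect: float = 0.5          # effect of the shared latent field on log grain
    beta0: tuple[float, float] = (-2.0, -2.3)  # teff, wheat intercepts (log mg/kg)
    true_soil_coefs: dict = field(default_factory=lambda: {
        "se_nit": 0.45, "se_pho": 0.35, "ph": 0.30,
    })
    seed: int = 20200901

    def __post_init__(self) -> None:
        if self.n_primary <= 0:
            raise ValueError("n_primary must be > 0")
        if not (0.0 < self.teff_fraction < 1.0):
            raise ValueError("teff fraction must lie in (0, 1)")
        lo, hi = self.close_pair_bounds_m
        if not (0.0 < lo < hi):
            raise ValueError("close-pair bounds must satisfy 0 < lower < upper")
        if self.n_close_pairs < 0:
            raise ValueError("n_close_pairs must be >= 0")
        if self.n_close_pairs > self.n_primary:
            raise ValueError("cannot have more close pairs than primary sites")
        if min(self.nugget_vars) < 0 or min(self.correlated_vars) < 0:
            raise ValueError("variances must be non-negative")

    def grain_coreg(self) -> Coregionalization:
        """True bivariate (teff, wheat) coregionalization of the grain residuals."""
        t = np.diag(self.nugget_vars)
        s1, s2 = self.correlated_vars
        r = self.grain_cross_corr
        S = np.array([[s1, r * math.sqrt(s1 * s2)], [r * math.sqrt(s1 * s2), s2]])
        mask = ~np.eye(2, dtype=bool)
        return Coregionalization(T=t, S=S, matern=MaternCorrelation(self.kappa, self.phi_km),
                                 nugget_zero_mask=mask)


def plot_layout() -> list[tuple[float, float]]:
    """Five sub-sample offsets (m) within the 100-m^2 circular field plot.

    Centre, two points on the long axis (along the crop rows) on the 100-
    and 75-m^2 subplot circumferences, and two on the short axis on the
    25- and 50-m^2 circumferences.  Radii r = sqrt(area/pi), to 2 dp.
    """
    r100 = round(math.sqrt(100.0 / math.pi), 2)   # 5.64
    r75 = round(math.sqrt(75.0 / math.pi), 2)     # 4.89
    r25 = round(math.sqrt(25.0 / math.pi), 2)     # 2.82
    r50 = round(math.sqrt(50.0 / math.pi), 2)     # 3.99
    return [(0.0, 0.0), (r100, 0.0), (-r75, 0.0), (0.0, r25), (0.0, -r50)]


def draw_design(config: SurveyConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Spread primary sites plus close-pair augmentation sites.

    The frame is stratified into ``n_primary`` roughly equal-area cells and
    one grid node is drawn uniformly per cell — a documented approximation
    to balanced-cube sampling that preserves the properties the analysis
    relies on (spread, near-uniform inclusion).  Close pairs are placed
    uniformly in the annulus around a spatially spread subset of primaries.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W, H = config.frame_km
    s = config.grid_spacing_km
    n = config.n_primary
    nx = max(int(round(math.sqrt(n * W / H))), 1)
    ny = int(math.ceil(n / nx))
    cw, ch = W / nx, H / ny
    if cw < s or ch < s:
        raise ValueError(
            f"frame too small: strata of {cw:.2f} x {ch:.2f} km cannot hold "
            f"grid nodes at {s} km spacing"
        )
    cells = [(i, j) for j in range(ny) for i in range(nx)]
    if len(cells) > n:
        drop = rng.choice(len(cells), size=len(cells) - n, replace=False)
        cells = [c for k, c in enumerate(cells) if k not in set(drop.tolist())]
    xs, ys = [], []
    def node_range(k, width, n_cells):
        lo = int(math.ceil(k * width / s - 1e-9))
        hi = int(math.floor(min((k + 1) * width, width * n_cells) / s + 1e-9))
        # boundary nodes belong to the lower stratum only, so strata never share
        if k < n_cells - 1 and hi * s >= (k + 1) * width - 1e-9:
            hi -= 1
        return lo, hi

    for i, j in cells:
        gx_lo, gx_hi = node_range(i, cw, nx)
        gy_lo, gy_hi = node_range(j, ch, ny)
        if gx_hi < gx_lo or gy_hi < gy_lo:
            raise ValueError("frame too small to hold a grid node in every stratum")
        xs.append(s * rng.integers(gx_lo, gx_hi + 1))
        ys.append(s * rng.integers(gy_lo, gy_hi + 1))
    pts = pd.DataFrame({"x_km": xs, "y_km": ys, "close_pair": False})

    if config.n_close_pairs > 0:
        # spread subset of primaries: evenly spaced through the stratum order
        idx = np.unique(np.round(np.linspace(0, n - 1, config.n_close_pairs)).astype(int))
        k = 0
        while len(idx) < config.n_close_pairs:  # de-duplication guard for tiny n
            if k not in idx:
                idx = np.sort(np.append(idx, k))
            k += 1
        lo, hi = (b / 1000.0 for b in config.close_pair_bounds_m)
        rows = []
        for i in idx[: config.n_close_pairs]:
            px, py = pts.loc[i, "x_km"], pts.loc[i, "y_km"]
            for _ in range(1000):
                r = math.sqrt(rng.uniform(lo**2, hi**2))
                th = rng.uniform(0.0, 2.0 * math.pi)
                qx, qy = px + r * math.cos(th), py + r * math.sin(th)
                if 0.0 <= qx <= W and 0.0 <= qy <= H:
                    rows.append({"x_km": qx, "y_km": qy, "close_pair": True,
                                 "pair_of": int(i)})
                    break
            else:  # pragma: no cover - frame >> annulus in any valid config
                raise RuntimeError("could not place close pair inside the frame")
        pts = pd.concat([pts, pd.DataFrame(rows)], ignore_index=True)
    pts["site_id"] = np.arange(len(pts))
    return pts[["site_id", "x_km", "y_km", "close_pair"] +
               (["pair_of"] if "pair_of" in pts else [])]


def simulate_fields(
    coords: np.ndarray,
    coreg: Coregionalization,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One joint draw (n_sites x p) of co-located coregionalized variables.

    The spatially correlated part is built from p independent copies of a
    unit Matérn field mixed by the Cholesky factor of S; the nugget part
    from iid normals mixed by the factor of T.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coreg.validate()
    coords = np.asarray(coords, dtype=float)
    n, p = len(coords), coreg.p
    from scipy.spatial.distance import cdist

    jitter = 1e-10 * np.eye(n)
    eps = 1e-12 * np.eye(p)
    if np.all(coreg.S == 0):
        corr_part = np.zeros((n, p))
    else:
        R = matern_corr(cdist(coords, coords), coreg.matern)
        Lr = np.linalg.cholesky(R + jitter)
        Ls = np.linalg.cholesky(coreg.S + eps)
        corr_part = (Lr @ rng.standard_normal((n, p))) @ Ls.T
    if np.all(coreg.T == 0):
        nug_part = np.zeros((n, p))
    else:
        Lt = np.linalg.cholesky(coreg.T + eps)
        nug_part = rng.standard_normal((n, p)) @ Lt.T
    out = corr_part + nug_part
    out[:, np.diag(coreg.S) + np.diag(coreg.T) == 0] = 0.0
    return out


def gaussian_field_grid(
    n_rows: int,
    n_cols: int,
    cell: float,
    corr,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance stationary Gaussian field on a grid by circulant embedding.

    ``corr`` maps distance to correlation.  Negative embedding eigenvalues
    (possible for very smooth models on small grids) are clipped to zero,
    which slightly deflates the variance; adequate for generating synthetic
    covariate surfaces.
    """
    m2, n2 = 2 * n_rows, 2 * n_cols
    iy = np.minimum(np.arange(m2), m2 - np.arange(m2))
    ix = np.minimum(np.arange(n2), n2 - np.arange(n2))
    d = cell * np.hypot(iy[:, None], ix[None, :])
    lam = np.fft.fft2(corr(d)).real
    lam = np.maximum(lam, 0.0)
    w = rng.standard_normal((m2, n2))
    f = np.fft.ifft2(np.fft.fft2(w) * np.sqrt(lam)).real
    return f[:n_rows, :n_cols]


@dataclass
class SyntheticSurvey:
    """A generated survey: sample table, covariate grids, and the truth record."""

    table: pd.DataFrame
    grids: dict[str, Grid]
    truth: dict
    config: SurveyConfig


def _transformed_scale(name: str, values: np.ndarray) -> np.ndarray:
    """Value of a soil property on the scale the transform rule will put it on."""
    loc, scale, lognormal = _SOIL_PARAMS[name]
    return np.log(values) if lognormal else values


def assemble_survey(config: SurveyConfig | None = None) -> SyntheticSurvey:
    """Generate a complete survey (design, soils, covariate grids, grain Se)."""
    config = config or SurveyConfig()
    rng = np.random.default_rng(config.seed)
    design = draw_design(config, rng)
    n = len(design)
    coords = design[["x_km", "y_km"]].to_numpy(float)
    W, H = config.frame_km

    # --- covariate grid geometry and latent fields -------------------------
    cell = config.covariate_cell_km
    n_cols = int(math.ceil(W / cell))
    n_rows = int(math.ceil(H / cell))
    long_corr = lambda d: matern_corr(d, MaternCorrelation(1.5, config.long_range_km / 3.0))
    short_corr = lambda d: np.exp(-d / config.short_range_km)
    latent = gaussian_field_grid(n_rows, n_cols, cell, long_corr, rng)
    other_long = gaussian_field_grid(n_rows, n_cols, cell, long_corr, rng)
    proto = Grid("latent", 0.0, 0.0, cell, latent)

    grids: dict[str, Grid] = {}
    for name in COVARIATE_NAMES:
        mean, sd, sh_lat, sh_other, sh_short = _COVARIATE_PARAMS[name]
        short = gaussian_field_grid(n_rows, n_cols, cell, short_corr, rng)
        nug_share = max(1.0 - sh_lat - sh_other - sh_short, 0.0)
        vals = mean + sd * (
            math.sqrt(sh_lat) * latent
            + math.sqrt(sh_other) * other_long
            + math.sqrt(sh_short) * short
            + math.sqrt(nug_share) * rng.standard_normal((n_rows, n_cols))
        )
        grids[name] = Grid(name, 0.0, 0.0, cell, vals)

    latent_at_sites = proto.values_at(coords[:, 0], coords[:, 1])

    # --- soil properties ---------------------------------------------------
    soil: dict[str, np.ndarray] = {}
    for name in SOIL_PROPERTIES:
        loc, scale, lognormal = _SOIL_PARAMS[name]
        load = _SOIL_LATENT_LOADING[name]
        z = load * latent_at_sites + math.sqrt(max(1.0 - load**2, 0.0)) \
            * rng.standard_normal(n)
        raw = loc + scale * z
        if lognormal:
            soil[name] = np.exp(raw)
        else:
            soil[name] = np.maximum(raw, 0.01) if name in ("soc", "total_oxides", "s_nit") \
                else raw

    # --- grain Se ----------------------------------------------------------
    crop = np.where(rng.random(n) < config.teff_fraction, "teff", "wheat")
    grain_fields = simulate_fields(coords, config.grain_coreg(), rng)
    mean_log = {"teff": np.full(n, config.beta0[0]), "wheat": np.full(n, config.beta0[1])}
    for name, coef in config.true_soil_coefs.items():
        t = _transformed_scale(name, soil[name])
        loc, scale, lognormal = _SOIL_PARAMS[name]
        centred = t - loc
        for c in mean_log:
            mean_log[c] = mean_log[c] + coef * centred
    for c in mean_log:
        mean_log[c] = mean_log[c] + config.latent_effect * latent_at_sites
    col = (crop == "wheat").astype(int)
    log_grain = np.where(
        crop == "teff", mean_log["teff"], mean_log["wheat"]
    ) + grain_fields[np.arange(n), col]
    grain_se = np.exp(log_grain)

    table = design.copy()
    table["crop"] = crop
    table["grain_se_mg_kg"] = grain_se
    for name in SOIL_PROPERTIES:
        table[name] = soil[name]

    truth = {
        "beta0_teff": config.beta0[0],
        "beta0_wheat": config.beta0[1],
        "true_soil_coefs": dict(config.true_soil_coefs),
        "latent_effect": config.latent_effect,
        "kappa": config.kappa,
        "phi_km": config.phi_km,
        "nugget_vars": tuple(config.nugget_vars),
        "correlated_vars": tuple(config.correlated_vars),
        "grain_cross_corr": config.grain_cross_corr,
        "latent_at_sites": latent_at_sites,
        "mean_log_teff": mean_log["teff"],
        "mean_log_wheat": mean_log["wheat"],
        "signal_covariates": [c for c in COVARIATE_NAMES
                              if _COVARIATE_PARAMS[c][2] > 0],
    }
    return SyntheticSurvey(table=table, grids=grids, truth=truth, config=config)


def write_survey(survey: SyntheticSurvey, outdir: str | Path) -> dict[str, Path]:
    """Write the sample table (CSV), covariate rasters (ESRI ASCII) and truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cols = ["site_id", "x_km", "y_km", "crop", "close_pair", "grain_se_mg_kg"] \
        + SOIL_PROPERTIES
    table_path = outdir / "sample_table.csv"
    survey.table[cols].to_csv(table_path, index=False)
    paths["table"] = table_path
    raster_paths = []
    for name in COVARIATE_NAMES:
        p = write_esri_ascii(survey.grids[name], outdir / f"{name}.asc")
        raster_paths.append(p)
        paths[name] = p
    paths["manifest"] = write_manifest(COVARIATE_NAMES, raster_paths,
                                       outdir / "covariates.manifest")
    truth_lines = []
    for key, val in survey.truth.items():
        if isinstance(val, np.ndarray):
            continue  # site-level arrays are test-harness objects, not artifacts
        truth_lines.append(f"{key} = {val}")
    (outdir / "truth.txt").write_text("\n".join(truth_lines) + "\n")
    paths["truth"] = outdir / "truth.txt"
    return paths
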