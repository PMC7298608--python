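"""Shared fixtures: small synthetic surveys and survey-like multivariate stacks."""

import numpy as np
import pandas as pd
import pytest

from graingeo.covariance import Coregionalization, MaternCorrelation
from graingeo.lmm import build_stack, univariate_stack
from graingeo.synthetic import SurveyConfig, assemble_survey, simulate_fields


@pytest.fixture
def rng():
    return np.random.default_rng(20200901)


@pytest.fixture(scope="session")
def small_survey():
    """A scaled-down survey used by schema and pipeline-level tests."""
    cfg = SurveyConfig(
        frame_km=(60.0, 60.0), n_primary=60, n_close_pairs=6,
        covariate_cell_km=3.0, seed=11,
    )
    return assemble_survey(cfg)


def grain_lmc_truth(kappa=2.0, phi=15.0):
    """Trivariate coregionalization with the structure of a fitted grain model:

    nugget correlations (0, 0.43, 0.20) with the teff-wheat entry a
    structural zero, correlated correlations (0.44, 0.52, 0.42).
    """
    t_corr = np.array([[1, 0, 0.43], [0, 1, 0.20], [0.43, 0.20, 1]])
    t_sd = np.sqrt([0.62, 0.92, 0.21])
    s_corr = np.array([[1, 0.44, 0.52], [0.44, 1, 0.42], [0.52, 0.42, 1]])
    s_sd = np.sqrt([0.39, 0.54, 0.25])
    mask = np.zeros((3, 3), bool)
    mask[0, 1] = mask[1, 0] = True
    return Coregionalization(
        T=t_corr * np.outer(t_sd, t_sd) * (~mask),
        S=s_corr * np.outer(s_sd, s_sd),
        matern=MaternCorrelation(kappa, phi),
        nugget_zero_mask=mask,
    )


def survey_coords(n, frame, rng, n_pairs=25):
    """Spread sites plus close pairs 100-1000 m away (survey collocation pattern)."""
    base = rng.uniform(0, frame, (n - n_pairs, 2))
    prim = base[rng.choice(len(base), n_pairs, replace=False)]
    r = np.sqrt(rng.uniform(0.1**2, 1.0**2, n_pairs))
    th = rng.uniform(0, 2 * np.pi, n_pairs)
    pairs = prim + np.column_stack([r * np.cos(th), r * np.sin(th)])
    return np.vstack([base, pairs])


def trivariate_stack(n, coreg, seed, frame=300.0, means=(1.0, 0.5, 0.8)):
    """Survey-pattern stack: y1 at teff sites, y2 at wheat sites, y3 everywhere."""
    rng = np.random.default_rng(seed)
    coords = survey_coords(n, frame, rng, n_pairs=min(25, n // 6))
    z = simulate_fields(coords, coreg, rng)
    crop = rng.random(n) < 0.5
    keep_by_var = [crop, ~crop, np.ones(n, bool)]
    frames = []
    for v, keep in enumerate(keep_by_var):
        frames.append(pd.DataFrame({
            "site_id": np.arange(n)[keep],
            "x_km": coords[keep, 0],
            "y_km": coords[keep, 1],
            "resp": z[keep, v] + means[v],
        }))
    return build_stack(frames, [[], [], []], "resp", var_names=["y1", "y2", "y3"])


def univariate_spatial_frame(n, seed, frame=300.0, tau2=0.5, sigma2=0.5,
                             phi=15.0, kappa=0.5, mean=1.0):
    """Single-variable spatial sample as a data frame ready for a stack."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, frame, (n, 2))
    coreg = Coregionalization([[tau2]], [[sigma2]], MaternCorrelation(kappa, phi))
    y = simulate_fields(coords, coreg, rng)[:, 0] + mean
    return pd.DataFrame({"site_id": np.arange(n), "x_km": coords[:, 0],
                         "y_km": coords[:, 1], "resp": y})


@pytest.fixture
def small_stack():
    df = univariate_spatial_frame(40, seed=5, frame=50.0)
    return univariate_stack(df, "resp")
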