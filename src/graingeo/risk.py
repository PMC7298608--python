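"""Threshold-shortfall probabilities and calibrated verbal categories.

Assuming normal prediction errors on the log scale, the probability that
the true grain concentration falls below a threshold t is
Phi((ln t - pred_log) / sqrt(PEV)).  Probabilities are mapped to a
calibrated likelihood language (config-overridable); the default bins are
<0.01 exceptionally unlikely, <0.10 very unlikely, <0.33 unlikely,
0.33-0.66 about as likely as not, >0.66 likely, >0.90 very likely,
>0.99 virtually certain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import rda_threshold
from .rasters import Grid

__all__ = ["VerbalScale", "RiskSurface", "prob_below", "verbal_category",
           "build_risk_surface", "DEFAULT_SCALE"]


@dataclass(frozen=True)
class VerbalScale:
    """Ordered (upper probability bound, phrase) bins; final bound is 1."""

    bins: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        phrases = [p for _, p in self.bins]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("bin bounds must be strictly increasing")
        if bounds[-1] != 1.0:
            raise ValueError("final bound must be 1")
        if len(set(phrases)) != len(phrases):
            raise ValueError("phrases must be unique")

    def category_index(self, p) -> np.ndarray:
        """Index of the bin containing p; bins are [lower, upper), top bin closed."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        bounds = np.array([b for b, _ in self.bins])
        idx = np.searchsorted(bounds, p, side="right")
        return np.minimum(idx, len(self.bins) - 1)

    def phrase(self, p):
        idx = self.category_index(p)
        phrases = np.array([ph for _, ph in self.bins])
        out = phrases[idx]
        return out if out.ndim else str(out)

    def legend(self) -> pd.DataFrame:
        lowers = [0.0] + [b for b, _ in self.bins[:-1]]
        return pd.DataFrame({
            "code": np.arange(len(self.bins)),
            "lower": lowers,
            "upper": [b for b, _ in self.bins],
            "phrase": [p for _, p in self.bins],
        })


DEFAULT_SCALE = VerbalScale(bins=(
    (0.01, "exceptionally unlikely"),
    (0.10, "very unlikely"),
    (0.33, "unlikely"),
    (0.66, "about as likely as not"),
    (0.90, "likely"),
    (0.99, "very likely"),
    (1.00, "virtually certain"),
))


def prob_below(pred_log, pev, threshold_mg_kg: float) -> np.ndarray:
    """P(concentration < threshold) under normal log-scale prediction errors.

    Zero PEV degenerates to the indicator of pred_log < ln(threshold).
    """
    if threshold_mg_kg <= 0:
        raise ValueError("threshold must be positive")
    pred_log = np.asarray(pred_log, dtype=float)
    pev = np.asarray(pev, dtype=float)
    if np.any(pev < 0):
        raise ValueError("PEV must be non-negative")
    lt = np.log(threshold_mg_kg)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (lt - pred_log) / np.sqrt(pev)
    p = norm.cdf(z)
    degenerate = pev == 0
    if np.any(degenerate):
        p = np.where(degenerate, (pred_log < lt).astype(float), p)
    return p if p.ndim else float(p)


def verbal_category(p, scale: VerbalScale = DEFAULT_SCALE):
    """Calibrated phrase for a shortfall probability."""
    return scale.phrase(p)


@dataclass
class RiskSurface:
    """Probability and verbal-category rasters with threshold provenance."""

    probability: Grid
    category: Grid  # integer-coded
    legend: pd.DataFrame
    threshold_mg_kg: float
    rda_ug_day: float
    serving_g_day: float
    metadata: dict = field(default_factory=dict)


def build_risk_surface(
    pred_grid: Grid,
    pev_grid: Grid,
    rda_ug_day: float = 55.0,
    serving_g_day: float = 300.0,
    scale: VerbalScale = DEFAULT_SCALE,
) -> RiskSurface:
    """Cellwise shortfall probability and category maps from prediction rasters."""
    if not pred_grid.same_geometry(pev_grid):
        raise ValueError("prediction and PEV rasters must share geometry")
    threshold = rda_threshold(rda_ug_day, serving_g_day)
    prob = prob_below(pred_grid.values, pev_grid.values, threshold)
    cat = scale.category_index(prob)
    return RiskSurface(
        probability=pred_grid.with_values(prob, name="prob_below_threshold"),
        category=pred_grid.with_values(cat.astype(float), name="verbal_category"),
        legend=scale.legend(),
        threshold_mg_kg=threshold,
        rda_ug_day=rda_ug_day,
        serving_g_day=serving_g_day,
        metadata={"threshold_mg_kg": threshold},
    )
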