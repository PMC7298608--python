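"""Variable transformations and derived soil indices applied before modelling.

Grain Se concentrations are always modelled on the natural-log scale.  Soil
properties are log-transformed only when their moment skewness coefficient
exceeds 1 (single pass; the rule is never re-applied to its own output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["skewness", "apply_transform_rule", "pbi", "rda_threshold", "TransformReport"]

SKEWNESS_THRESHOLD = 1.0


def skewness(values) -> float:
    """Moment skewness m3 / m2^(3/2), biased (1/n) moments, no small-sample factor."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("skewness requires finite values")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        raise ValueError("skewness undefined for a zero-variance sample")
    return float(np.mean(d**3) / m2**1.5)


@dataclass
class TransformReport:
    """Per-variable record of the skewness-based log-transform decision."""

    table: pd.DataFrame  # columns: variable, skewness, transformed, transform

    def transformed_variables(self) -> list[str]:
        return list(self.table.loc[self.table["transformed"], "variable"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransformReport":
        return cls(pd.read_csv(path))


def apply_transform_rule(
    soil: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = SKEWNESS_THRESHOLD,
) -> tuple[pd.DataFrame, TransformReport]:
    """Log-transform each column whose skewness exceeds ``threshold``.

    Returns a copy of the table with selected columns replaced by their
    natural logarithms, plus a :class:`TransformReport` listing every
    decision.  Values of a column selected for transformation must be
    strictly positive.
    """
    columns = list(columns) if columns is not None else list(soil.columns)
    out = soil.copy()
    rows = []
    for col in columns:
        sk = skewness(soil[col].to_numpy())
        transform = sk > threshold
        if transform:
            vals = soil[col].to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValueError(
                    f"variable {col!r} selected for log-transform has non-positive values"
                )
            out[col] = np.log(vals)
        rows.append(
            {
                "variable": col,
                "skewness": sk,
                "transformed": transform,
                "transform": "natural log" if transform else "none",
            }
        )
    return out, TransformReport(pd.DataFrame(rows))


def pbi(p_sorbed: float, p_olsen: float, p_solution: float) -> float:
    """Phosphorus buffer index (single-addition form).

    PBI = (Ps + 4.59 * P_Olsen) / Pc^0.41, with Ps the sorbed P
    (mg P/kg soil), P_Olsen the bicarbonate-extractable P (mg P/kg) and Pc
    the final solution P concentration (mg P/L).
    """
    if p_solution <= 0:
        raise ValueError("p_solution must be > 0")
    if p_sorbed < 0 or p_olsen < 0:
        raise ValueError("p_sorbed and p_olsen must be >= 0")
    return (p_sorbed + 4.59 * p_olsen) / p_solution**0.41


def rda_threshold(rda_ug_day: float = 55.0, serving_g_day: float = 300.0) -> float:
    """Grain concentration (mg/kg) below which a daily serving misses the RDA.

    ``rda_ug_day`` in ug/day, ``serving_g_day`` in g/day; ug/g == mg/kg, so
    the threshold is simply rda/serving, reported to 3 decimal places
    (55 ug/day over a 300-g serving gives 0.183 mg/kg).
    """
    if serving_g_day <= 0:
        raise ValueError("serving must be > 0")
    if rda_ug_day < 0:
        raise ValueError("rda must be >= 0")
    return round(rda_ug_day / serving_g_day, 3)
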