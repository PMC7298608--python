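"""Declarative configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import COVARIATE_NAMES, SOIL_PROPERTIES

__all__ = ["PipelineConfig", "load_config", "SOIL_ORDER", "COVARIATE_ORDER"]

# a priori test orderings, fixed before any response data are seen
SOIL_ORDER: list[str] = list(SOIL_PROPERTIES)
COVARIATE_ORDER: list[str] = list(COVARIATE_NAMES)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializable to/from YAML."""

    outdir: str = "graingeo_run"
    sample_table: str | None = None        # None -> simulate a synthetic survey
    covariate_manifest: str | None = None
    crop: str = "teff"
    soil_order: list[str] = field(default_factory=lambda: list(SOIL_ORDER))
    covariate_order: list[str] = field(default_factory=lambda: list(COVARIATE_ORDER))
    skew_threshold: float = 1.0
    fdr_wealth: float = 0.05
    fdr_payout: float = 0.05
    kappa_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 1.0, 1.5, 2.0, 3.0])
    selection_kappa: float = 0.5
    rda_ug_day: float = 55.0
    serving_g_day: float = 300.0
    fit_starts: int = 3
    seed: int = 20200901
    log_level: str = "INFO"
    # synthetic-survey knobs (used only when no sample table is supplied)
    n_primary: int = 475
    n_close_pairs: int = 25
    frame_km: float = 300.0
    covariate_cell_km: float = 2.0

    def __post_init__(self) -> None:
        for name, order in [("soil_order", self.soil_order),
                            ("covariate_order", self.covariate_order)]:
            if not order:
                raise ValueError(f"{name} must be non-empty")
            if len(set(order)) != len(order):
                raise ValueError(f"{name} contains duplicates")
        unknown = set(self.soil_order) - set(SOIL_PROPERTIES)
        if unknown:
            raise ValueError(f"unknown soil labels in ordering: {sorted(unknown)}")
        if self.crop not in ("teff", "wheat"):
            raise ValueError("crop must be 'teff' or 'wheat'")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
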