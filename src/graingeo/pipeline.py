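"""End-to-end orchestration of the mapping pipeline.

Stage order: transform -> soil selection -> soil-predicted grain (y3) ->
covariate selection -> factorial-kriging decomposition and component
filtering -> kappa profile -> trivariate REML fit -> LOOCV (OK and E-BLUP)
-> grid prediction -> risk maps.  Every stage writes its artifacts into the
output directory and appends an entry (seed, input/output hashes) to
``manifest.json``; a re-run with ``resume=True`` reloads completed stages
from disk, and the hash chain lets tampering be detected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fka, plots, risk, selection, synthetic, validation
from .config import PipelineConfig
from .covariance import Coregionalization, MaternCorrelation, empirical_variogram
from .lmm import LMMFit, build_stack, fit_lmm, profile_kappa, univariate_stack
from .prediction import eblup_predict
from .preprocess import apply_transform_rule
from .rasters import Grid, read_esri_ascii, read_manifest, write_esri_ascii

logger = logging.getLogger("graingeo")

STAGES = ["simulate", "transform", "select-soil", "select-covariates", "fka",
          "kappa", "fit", "crossval", "predict", "riskmap"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _fit_to_dict(fit: LMMFit) -> dict:
    return {
        "labels": fit.labels,
        "beta": fit.beta.tolist(),
        "beta_se": fit.beta_se.tolist(),
        "T": fit.coreg.T.tolist(),
        "S": fit.coreg.S.tolist(),
        "mask01": bool(fit.coreg.nugget_zero_mask is not None),
        "kappa": fit.kappa,
        "phi": fit.phi,
        "loglik": fit.loglik,
        "method": fit.method,
        "n_obs": fit.n_obs,
    }


def _fit_from_dict(d: dict) -> LMMFit:
    p = len(d["T"])
    mask = None
    if d.get("mask01") and p >= 2:
        mask = np.zeros((p, p), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
    coreg = Coregionalization(T=np.array(d["T"]), S=np.array(d["S"]),
                              matern=MaternCorrelation(d["kappa"], d["phi"]),
                              nugget_zero_mask=mask)
    return LMMFit(labels=d["labels"], beta=np.array(d["beta"]),
                  beta_se=np.array(d["beta_se"]), coreg=coreg,
                  loglik=d["loglik"], method=d["method"], n_obs=d["n_obs"])


class Pipeline:
    """Disk-backed pipeline runner; any stage is resumable from its artifacts."""

    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if resume and self.manifest_path.exists() else {"stages": []}
        )
        logging.basicConfig(
            level=getattr(logging, config.log_level.upper(), logging.INFO),
            format="%(asctime)s %(name)s %(levelname)s %(message)s",
        )

    # -- manifest plumbing --------------------------------------------------

    def _record(self, stage: str, seed: int, inputs: list[Path], outputs: list[Path]):
        entry = {
            "stage": stage,
            "seed": seed,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        self.manifest["stages"] = [s for s in self.manifest["stages"]
                                   if s["stage"] != stage] + [entry]
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _done(self, stage: str) -> bool:
        if not self.resume:
            return False
        for s in self.manifest["stages"]:
            if s["stage"] == stage:
                return all(Path(p).exists() and _sha256(Path(p)) == h
                           for p, h in s["outputs"].items())
        return False

    def verify(self) -> bool:
        """Re-hash every recorded artifact; False if anything was tampered with."""
        for s in self.manifest["stages"]:
            for p, h in {**s["inputs"], **s["outputs"]}.items():
                if not Path(p).exists() or _sha256(Path(p)) != h:
                    return False
        return True

    # -- stages -------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        ctx: dict = {}
        for stage in stages or STAGES:
            method = getattr(self, "stage_" + stage.replace("-", "_"))
            logger.info("stage %s (seed %d)", stage, self.cfg.seed)
            try:
                method(ctx)
            except Exception:
                logger.exception("stage %s failed; completed-stage manifest kept", stage)
                raise
        return ctx

    def stage_simulate(self, ctx: dict):
        cfg = self.cfg
        survey_dir = self.out / "survey"
        if cfg.sample_table is not None:
            table = pd.read_csv(cfg.sample_table)
            grids = {}
            if cfg.covariate_manifest:
                mdir = Path(cfg.covariate_manifest).parent
                for name, fname in read_manifest(cfg.covariate_manifest):
                    grids[name] = read_esri_ascii(mdir / fname, name)
            ctx["table"], ctx["grids"] = table, grids
            return
        if self._done("simulate"):
            ctx["table"] = pd.read_csv(survey_dir / "sample_table.csv")
            ctx["grids"] = {name: read_esri_ascii(survey_dir / fname, name)
                            for name, fname in read_manifest(survey_dir / "covariates.manifest")}
            return
        sc = synthetic.SurveyConfig(
            frame_km=(cfg.frame_km, cfg.frame_km), n_primary=cfg.n_primary,
            n_close_pairs=cfg.n_close_pairs, covariate_cell_km=cfg.covariate_cell_km,
            seed=cfg.seed,
        )
        survey = synthetic.assemble_survey(sc)
        paths = synthetic.write_survey(survey, survey_dir)
        ctx["table"], ctx["grids"] = survey.table, survey.grids
        ctx["truth"] = survey.truth
        self._record("simulate", cfg.seed, [], list(paths.values()))

    def stage_transform(self, ctx: dict):
        cfg = self.cfg
        table = ctx["table"]
        soils = [c for c in cfg.soil_order if c in table.columns]
        transformed, report = apply_transform_rule(table, soils, cfg.skew_threshold)
        transformed["log_grain_se"] = np.log(table["grain_se_mg_kg"].to_numpy(float))
        # covariate values extracted from the containing grid cell at each site
        for name, grid in ctx["grids"].items():
            transformed[name] = grid.values_at(table["x_km"].to_numpy(),
                                               table["y_km"].to_numpy())
        out_table = self.out / "table_transformed.csv"
        transformed.to_csv(out_table, index=False)
        report.to_csv(self.out / "transform_report.csv")
        ctx["data"], ctx["transform_report"] = transformed, report
        self._record("transform", cfg.seed, [], [out_table, self.out / "transform_report.csv"])

    def _target_frame(self, ctx) -> pd.DataFrame:
        return ctx["data"][ctx["data"]["crop"] == self.cfg.crop].reset_index(drop=True)

    def stage_select_soil(self, ctx: dict):
        cfg = self.cfg
        df = self._target_frame(ctx)
        stack = univariate_stack(df, "log_grain_se")
        res = selection.select_soil_predictors(
            stack, df, cfg.soil_order, kappa=cfg.selection_kappa,
            w0=cfg.fdr_wealth, payout=cfg.fdr_payout,
        )
        res.ledger.to_csv(self.out / "soil_ledger.csv")
        (self.out / "soil_selected.txt").write_text("\n".join(res.selected) + "\n")
        plots.plot_ledger(res.ledger, self.out / "soil_selection.png")
        y3 = selection.predict_from_soil(res.fit, ctx["data"])
        ctx["data"] = ctx["data"].assign(y3=y3)
        ctx["data"].to_csv(self.out / "y3.csv", index=False)
        ctx["soil_selection"] = res
        self._record("select-soil", cfg.seed, [self.out / "table_transformed.csv"],
                     [self.out / "soil_ledger.csv", self.out / "soil_selected.txt",
                      self.out / "y3.csv"])

    def stage_select_covariates(self, ctx: dict):
        cfg = self.cfg
        df = self._target_frame(ctx)
        order = [c for c in cfg.covariate_order if c in df.columns]
        stack = univariate_stack(df, "log_grain_se")
        res = selection.select_covariates(
            stack, df, order, kappa=cfg.selection_kappa,
            w0=cfg.fdr_wealth, payout=cfg.fdr_payout,
        )
        res.ledger.to_csv(self.out / "cov_ledger.csv")
        (self.out / "cov_selected.txt").write_text("\n".join(res.selected) + "\n")
        plots.plot_ledger(res.ledger, self.out / "cov_selection.png")
        ctx["cov_selection"] = res
        self._record("select-covariates", cfg.seed, [self.out / "table_transformed.csv"],
                     [self.out / "cov_ledger.csv", self.out / "cov_selected.txt"])

    def stage_fka(self, ctx: dict):
        """Decompose selected covariates by scale and screen the components."""
        cfg = self.cfg
        selected = ctx["cov_selection"].selected
        data = ctx["data"]
        comp_grids: dict[str, Grid] = {}
        site_comps = pd.DataFrame(index=data.index)
        outputs = []
        rng = np.random.default_rng(cfg.seed + 1)
        for name in selected:
            grid = ctx["grids"][name]
            gx, gy = grid.cell_centers()
            vals = grid.values.ravel()
            # variogram on a random subsample of cells (pair count control)
            take = rng.choice(len(vals), size=min(1200, len(vals)), replace=False)
            ev = empirical_variogram(vals[take], np.column_stack([gx, gy])[take])
            model = fka.fit_nested_variogram(ev)
            ev.to_frame().to_csv(self.out / f"{name}_variogram.csv", index=False)
            outputs.append(self.out / f"{name}_variogram.csv")
            # component surfaces kriged from the subsample, evaluated on grid + sites
            dcoords = np.column_stack([gx, gy])[take]
            dvals = vals[take]
            targets_grid = np.column_stack([gx, gy])
            targets_sites = data[["x_km", "y_km"]].to_numpy(float)
            for comp, tag in [(0, "short"), (1, "long"), ("mean", "mean")]:
                surf = fka.krige_component(dvals, dcoords, model, comp, targets_grid)
                at_sites = fka.krige_component(dvals, dcoords, model, comp, targets_sites)
                if tag == "mean":
                    # the local mean travels with the long-range component
                    comp_grids[f"{name}__long"] = comp_grids[f"{name}__long"].with_values(
                        comp_grids[f"{name}__long"].values + surf.reshape(grid.shape))
                    site_comps[f"{name}__long"] += at_sites
                else:
                    comp_grids[f"{name}__{tag}"] = grid.with_values(
                        surf.reshape(grid.shape), f"{name}__{tag}")
                    site_comps[f"{name}__{tag}"] = at_sites
        # screen components as fixed effects for the target grain
        df = self._target_frame(ctx)
        t_idx = data.index[data["crop"] == cfg.crop]
        stack = univariate_stack(df, "log_grain_se")
        cand = site_comps.loc[t_idx].reset_index(drop=True)
        retained, _ = fka.filter_components(stack, cand, kappa=cfg.selection_kappa) \
            if len(cand.columns) else ([], None)
        for col in site_comps.columns:
            ctx["data"][col] = site_comps[col]
        for key in list(comp_grids):
            if key not in retained:
                pass  # grids kept on disk for inspection even when screened out
            outputs.append(write_esri_ascii(comp_grids[key], self.out / f"{key}.asc"))
        (self.out / "retained_components.txt").write_text("\n".join(retained) + "\n")
        outputs.append(self.out / "retained_components.txt")
        ctx["retained_components"] = retained
        ctx["component_grids"] = comp_grids
        self._record("fka", cfg.seed, [self.out / "cov_selected.txt"], outputs)

    def stage_kappa(self, ctx: dict):
        cfg = self.cfg
        df = self._target_frame(ctx)
        preds = ctx.get("retained_components", [])
        stack = univariate_stack(df, "log_grain_se", preds)
        best, table = profile_kappa(stack, cfg.kappa_grid, method="ML")
        table.to_csv(self.out / "kappa_profile.csv", index=False)
        (self.out / "kappa.txt").write_text(f"{best}\n")
        ctx["kappa"] = best
        self._record("kappa", cfg.seed, [], [self.out / "kappa_profile.csv",
                                             self.out / "kappa.txt"])

    def stage_fit(self, ctx: dict):
        cfg = self.cfg
        data = ctx["data"]
        preds = ctx.get("retained_components", [])
        target = data[data["crop"] == cfg.crop].reset_index(drop=True)
        other = data[data["crop"] != cfg.crop].reset_index(drop=True)
        soil_pred = data.reset_index(drop=True).rename(columns={"y3": "resp"})
        target = target.rename(columns={"log_grain_se": "resp"})
        other = other.rename(columns={"log_grain_se": "resp"})
        stack = build_stack(
            [target, other, soil_pred],
            predictors=[preds, [], preds],
            response="resp",
            var_names=["y1", "y2", "y3"],
        )
        fit = fit_lmm(stack, method="REML", kappa=ctx.get("kappa", 2.0),
                      n_starts=cfg.fit_starts)
        (self.out / "fit_summary.txt").write_text(fit.summary() + "\n")
        (self.out / "fit.json").write_text(json.dumps(_fit_to_dict(fit), indent=1))
        ctx["fit"], ctx["stack"] = fit, stack
        self._record("fit", cfg.seed, [], [self.out / "fit_summary.txt",
                                           self.out / "fit.json"])

    def stage_crossval(self, ctx: dict):
        cfg = self.cfg
        fit, stack = ctx["fit"], ctx["stack"]
        rep_eblup = validation.loocv(stack, fit, "EBLUP", interval_seed=cfg.seed)
        rep_ok = validation.loocv(stack, fit, "OK", interval_seed=cfg.seed)
        rep_eblup.to_csv(self.out / "crossval_eblup.csv")
        rep_ok.to_csv(self.out / "crossval_ok.csv")
        summary = pd.DataFrame([rep_ok.summary(), rep_eblup.summary()])
        summary.to_csv(self.out / "crossval_summary.csv", index=False)
        target = ctx["data"][ctx["data"]["crop"] == cfg.crop]
        plots.plot_crossval(rep_eblup, target[["x_km", "y_km"]].to_numpy(float),
                            self.out / "crossval_eblup.png")
        ctx["crossval"] = {"EBLUP": rep_eblup, "OK": rep_ok}
        self._record("crossval", cfg.seed, [self.out / "fit.json"],
                     [self.out / "crossval_eblup.csv", self.out / "crossval_ok.csv",
                      self.out / "crossval_summary.csv"])

    def stage_predict(self, ctx: dict):
        cfg = self.cfg
        fit, stack = ctx["fit"], ctx["stack"]
        preds = ctx.get("retained_components", [])
        grids = ctx["grids"]
        proto = next(iter(ctx.get("component_grids", {}).values()), None) \
            or next(iter(grids.values()))
        gx, gy = proto.cell_centers()
        targets = pd.DataFrame({"x_km": gx, "y_km": gy})
        for name in preds:
            targets[name] = ctx["component_grids"][name].values.ravel()
        res = eblup_predict(fit, stack, targets, var_prefix="y1", hull_warn=False)
        outputs = []
        for name, vals in [("eblup_log", res.pred_log), ("pev_log", res.pev),
                           ("median_mg_kg", res.median)]:
            g = proto.with_values(vals.reshape(proto.shape), name)
            outputs.append(write_esri_ascii(g, self.out / f"{name}.asc"))
        ctx["prediction"] = res
        ctx["pred_grids"] = {
            "eblup_log": proto.with_values(res.pred_log.reshape(proto.shape), "eblup_log"),
            "pev_log": proto.with_values(res.pev.reshape(proto.shape), "pev_log"),
        }
        self._record("predict", cfg.seed, [self.out / "fit.json"], outputs)

    def stage_riskmap(self, ctx: dict):
        cfg = self.cfg
        surface = risk.build_risk_surface(
            ctx["pred_grids"]["eblup_log"], ctx["pred_grids"]["pev_log"],
            rda_ug_day=cfg.rda_ug_day, serving_g_day=cfg.serving_g_day,
        )
        outputs = [
            write_esri_ascii(surface.probability, self.out / "prob_below_threshold.asc"),
            write_esri_ascii(surface.category, self.out / "verbal_category.asc"),
        ]
        surface.legend.to_csv(self.out / "verbal_legend.csv", index=False)
        outputs.append(self.out / "verbal_legend.csv")
        meta = {"threshold_mg_kg": surface.threshold_mg_kg,
                "rda_ug_day": cfg.rda_ug_day, "serving_g_day": cfg.serving_g_day}
        (self.out / "risk_metadata.json").write_text(json.dumps(meta, indent=1))
        outputs.append(self.out / "risk_metadata.json")
        ctx["risk"] = surface
        self._record("riskmap", cfg.seed, [], outputs)


def run_pipeline(config: PipelineConfig, resume: bool = False,
                 stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns the in-memory artifact bundle."""
    return Pipeline(config, resume=resume).run(stages)
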