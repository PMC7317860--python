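"""End-to-end orchestration: ingest -> anomaly -> DINEOF -> EOF -> COG -> RF.

A run is configured by :class:`RunConfig`, executes the analysis stages in
order, and produces a :class:`RunSummary` holding per-stage record counts
and the headline statistics (COG slopes, PC correlations, variance
fractions, RF variance explained and importance ranking).  A single global
seed fans out to per-stage seeds by fixed offsets so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import RegionBox, STUDY_REGION
from .cog_analysis import annual_mean, cog_series, cog_trend, correlate
from .dineof import dineof_fill, select_reconstructable
from .driver_models import fit_rf, gvif, partial_dependence, permutation_importance
from .eof_core import eof, pc_correlation
from .errors import EffortShiftError
from .grid_ingest import (
    aggregate_effort,
    compute_anomaly,
    fad_catch_proportion,
    linear_trend,
    read_effort_table,
    read_ssta_table,
    regional_mean_series,
    subset_region,
)
from .synthetic import SyntheticConfig, generate_all, generate_covariates

log = logging.getLogger(__name__)

# fixed per-stage seed offsets (recorded in the summary)
STAGE_SEED_OFFSETS = {"simulate": 0, "dineof": 101, "rf_effort": 202, "rf_pc1": 303}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    years: tuple = (1991, 2017)
    box: RegionBox = STUDY_REGION
    effort_csv: str | None = None  # None -> simulate
    ssta_csv: str | None = None
    outdir: str | None = None
    # DINEOF
    max_missing_frac: float = 0.25
    dineof_k_max: int = 10
    dineof_cv_frac: float = 0.05
    dineof_tol: float = 1e-5
    # EOF
    n_modes: int = 3
    k_max_lc: int = 3
    # RF
    rf_n_trees: int = 1000
    rf_mtry: int | None = None
    # synthetic conditions (used when no input files are given)
    synthetic: SyntheticConfig | None = None

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 17 + STAGE_SEED_OFFSETS.get(stage, 0)) % (2 ** 31)


@dataclass
class RunSummary:
    """Serializable record of a pipeline run."""

    stages: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "stages": self.stages,
            "stats": self.stats,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Period):
        return str(obj)
    return str(obj)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), default=_json_default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages in order; any failure aborts with the stage name."""
    summary = RunSummary(config_hash=_config_hash(config))
    summary.seeds = {s: config.stage_seed(s) for s in STAGE_SEED_OFFSETS}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        # 1 --- inputs: simulate or ingest ------------------------------------
        truths = None
        if config.effort_csv is None:
            syn_cfg = config.synthetic or SyntheticConfig()
            syn_cfg.seed = config.stage_seed("simulate")
            syn_cfg.years = tuple(config.years)
            bundle = generate_all(syn_cfg)
            records, n_rejected = bundle.effort_records, 0
            ssta_cube = bundle.ssta_cube
            truths = bundle
            summary.add_stage(
                "inputs", source="synthetic", n_records=len(records),
                n_masked=int(len(bundle.effort_truth.masked)),
            )
        else:
            records, n_rejected = read_effort_table(config.effort_csv)
            if config.ssta_csv is None:
                raise EffortShiftError("ssta_csv is required when effort_csv is given")
            ssta_cube = read_ssta_table(config.ssta_csv, box=config.box,
                                        period=tuple(config.years))
            summary.add_stage(
                "inputs", source="files", n_records=len(records), n_rejected=n_rejected
            )

        # 2 --- region subset + aggregation -----------------------------------
        stage = "aggregate"
        records = subset_region(records, config.box)
        cube1 = aggregate_effort(records, 1, config.box, tuple(config.years))
        cube5 = aggregate_effort(records, 5, config.box, tuple(config.years))
        summary.add_stage(
            "aggregate",
            n_records_in_region=len(records),
            n_quarters=cube5.n_quarters,
            total_effort_hours=float(np.nansum(cube5.values)),
        )

        # 3 --- regional SSTA series + trend ----------------------------------
        stage = "ssta_series"
        ssta_series = regional_mean_series(ssta_cube, config.box)
        trend = linear_trend(ssta_series)
        summary.stats["ssta_trend_slope_per_quarter"] = trend.slope
        summary.stats["ssta_trend_total_change"] = trend.total_change
        summary.stats["ssta_trend_p_value"] = trend.p_value
        summary.add_stage("ssta_series", n_quarters=int(ssta_series.notna().sum()))

        # 4 --- centre of gravity ---------------------------------------------
        stage = "cog"
        cog_frames = []
        annual_ssta = annual_mean(ssta_series)
        for hemi in ("north", "south"):
            series = cog_series(records, hemi)
            fitres = cog_trend(series)
            corr = correlate(series.to_series(), annual_ssta)
            summary.stats[f"cog_{hemi}_slope_deg_per_year"] = fitres.slope
            summary.stats[f"cog_{hemi}_trend_p_value"] = fitres.p_value
            summary.stats[f"cog_{hemi}_ssta_r"] = corr.r
            summary.stats[f"cog_{hemi}_ssta_p_value"] = corr.p_value
            cog_frames.append(series.to_frame())
        cog_table = pd.concat(cog_frames, ignore_index=True)
        if outdir:
            cog_table.to_csv(outdir / "cog.csv", index=False)
        summary.add_stage("cog", n_years=int(cog_table["year"].nunique()))

        # 5 --- effort anomaly, selection, DINEOF ------------------------------
        stage = "dineof"
        anomalies = compute_anomaly(cube5)
        selected = select_reconstructable(anomalies, config.max_missing_frac)
        dres = dineof_fill(
            selected,
            k_max=config.dineof_k_max,
            cv_frac=config.dineof_cv_frac,
            tol=config.dineof_tol,
            seed=config.stage_seed("dineof"),
        )
        summary.stats["dineof_k_opt"] = dres.k_opt
        summary.add_stage(
            "dineof",
            n_columns_selected=selected.n_space,
            n_columns_dropped=anomalies.n_space - selected.n_space,
            k_opt=dres.k_opt,
            converged=dres.converged,
        )

        # 6 --- EOF decompositions + PC correlation ----------------------------
        stage = "eof"
        effort_eof = eof(dres.filled, k_max_lc=config.k_max_lc)
        ssta_anom = compute_anomaly(ssta_cube)
        ssta_eof = eof(ssta_anom, k_max_lc=config.k_max_lc)
        corr = pc_correlation(effort_eof, ssta_eof, 1, 1)
        summary.stats["effort_eof_var_frac"] = effort_eof.var_frac[: config.n_modes]
        summary.stats["ssta_eof_var_frac"] = ssta_eof.var_frac[: config.n_modes]
        summary.stats["pc1_correlation_r"] = corr.r
        summary.stats["pc1_correlation_p_value"] = corr.p_value
        if outdir:
            effort_eof.pc_series(1).to_frame().join(
                ssta_eof.pc_series(1), how="inner", rsuffix="_ssta"
            ).to_csv(outdir / "pc1.csv")
        summary.add_stage(
            "eof",
            effort_modes=effort_eof.n_modes,
            ssta_modes=ssta_eof.n_modes,
            pc1_r=corr.r,
        )

        # 7 --- covariates, GVIF, random forests -------------------------------
        stage = "random_forest"
        effort_total = pd.Series(
            np.nansum(cube5.values.reshape(cube5.n_quarters, -1), axis=1),
            index=cube5.time_index,
        )
        fad = fad_catch_proportion(records)
        if truths is not None:
            cov_cfg = truths.config
        else:
            cov_cfg = SyntheticConfig(seed=config.stage_seed("simulate"),
                                      years=tuple(config.years))
        table, _ = generate_covariates(
            cov_cfg,
            ssta_series=ssta_series,
            fad_prop=fad,
            effort_series=effort_total,
            pc1_series=effort_eof.pc_series(1),
        )
        gv = gvif(table)
        summary.stats["gvif_max"] = float(
            gv.table.loc[np.isfinite(gv.table["gvif"]), "gvif"].max()
        )
        rf_stats = {}
        for resp in ("effort", "pc1"):
            fit = fit_rf(
                table,
                response=resp,
                n_trees=config.rf_n_trees,
                mtry=config.rf_mtry,
                seed=config.stage_seed(f"rf_{resp}"),
            )
            imp = permutation_importance(fit)
            rf_stats[resp] = {
                "var_explained": fit.var_explained,
                "importance": imp.to_dict(),
                "top_predictors": list(imp.index[:3]),
            }
            if outdir:
                imp.rename_axis("predictor").to_csv(outdir / f"importance_{resp}.csv")
                pd.concat(
                    {
                        p: partial_dependence(fit, p)
                        for p in list(imp.index[:3])
                    },
                    names=["predictor", "i"],
                ).to_csv(outdir / f"pdp_{resp}.csv")
        summary.stats["rf"] = rf_stats
        summary.add_stage(
            "random_forest",
            n_rows=len(table.dropna()),
            gvif_flagged=gv.flagged,
        )

        # 8 --- summary --------------------------------------------------------
        stage = "summary"
        summary.add_stage("summary", n_stats=len(summary.stats))
        if outdir:
            summary.to_json(outdir / "run_summary.json")
    except Exception as exc:
        raise EffortShiftError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return summary
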