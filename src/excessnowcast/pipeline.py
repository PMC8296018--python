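"""End-to-end orchestration: data -> delay fits -> outliers -> nowcast ->
baseline -> excess -> covariate regression.

A single :class:`PipelineConfig` drives the run; every stage writes CSV/JSON
artifacts into the output directory and is recorded, with SHA-256 checksums
and its seed, in ``manifest.json``.  Reruns with an identical config and
seed reproduce all stochastic outputs draw-for-draw (sub-seeds are derived
deterministically from the global seed), and a completed identical run is
not recomputed (whole-run caching on the config hash).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from . import inference as inf
from . import nowcast as ncmod
from . import regression as reg
from .mmwr import (
    HistoricalSeries,
    SnapshotSeries,
    read_historical_csv,
    read_snapshot_csv,
    write_historical_csv,
    write_snapshot_csv,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("excessnowcast")


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``simulation`` or the input paths must be set."""

    out_dir: str = "excessnowcast-run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    snapshot_csvs: tuple[tuple[str, str], ...] = ()   # (ISO pub date, path)
    historical_csv: str | None = None
    covariate_csv: str | None = None
    nowcast_delay_model: str = "nonparametric"        # or a parametric family
    outlier_threshold: float = 0.025
    periods: tuple[tuple[str, int, int], ...] = (
        ("mar_dec", *bl.PERIOD_MAR_DEC),
        ("sep_dec", *bl.PERIOD_SEP_DEC),
    )
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 500
    nowcast_draws: int = 1000
    cache: bool = True

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = bool(self.snapshot_csvs) and self.historical_csv is not None
        if has_sim == has_paths:
            raise ValueError("set exactly one of simulation config or input paths")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (excludes out_dir/cache)."""
        d = _jsonable(self)
        d.pop("out_dir", None)
        d.pop("cache", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (dt.date, Path)):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subseed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        sim_cfg = dataclasses.replace(cfg.simulation, rng_seed=_subseed(cfg.seed, "simulate"))
        ds = simulate_dataset(sim_cfg)
        return ds.series, ds.historical, ds.covariates, ds.truth
    snaps = [
        read_snapshot_csv(path, dt.date.fromisoformat(date))
        for date, path in cfg.snapshot_csvs
    ]
    series = SnapshotSeries(snaps)
    historical = read_historical_csv(cfg.historical_csv)
    covariates = pd.read_csv(cfg.covariate_csv) if cfg.covariate_csv else None
    return series, historical, covariates, None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in dependency order; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = cfg.config_hash()
    if cfg.cache and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and all(
            (out / f).exists() for st in old["stages"].values() for f in st["files"]
        ):
            log.info("[cache] config unchanged; reusing %s", out)
            return out

    manifest: dict = {"config_hash": chash, "seed": cfg.seed,
                      "config": _jsonable(cfg), "stages": {}}

    def record(stage: str, files: dict[str, str], **diag) -> None:
        manifest["stages"][stage] = {
            "files": {fname: _sha256(out / fname) for fname in files.values()},
            **diag,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        log.info("[%s] done: %s", stage, ", ".join(files.values()))

    try:
        # ---- stage: data ------------------------------------------------
        series, historical, covariates, truth = _load_inputs(cfg)
        jurisdictions = series.jurisdictions
        write_snapshot_csv(series.final, out / "final_snapshot.csv")
        write_historical_csv(historical, out / "historical.csv")
        files = {"final_snapshot": "final_snapshot.csv", "historical": "historical.csv"}
        if covariates is not None:
            covariates.to_csv(out / "covariates.csv", index=False)
            files["covariates"] = "covariates.csv"
        if truth is not None:
            truth.delay_params.to_csv(out / "true_delay_params.csv", index=False)
            files["true_delay_params"] = "true_delay_params.csv"
        record("data", files, n_snapshots=len(series), n_jurisdictions=len(jurisdictions))

        # ---- stage: delay fits ------------------------------------------
        seed = _subseed(cfg.seed, "delays")
        mcmc = dict(n_chains=cfg.n_chains, n_warmup=cfg.n_warmup, n_draws=cfg.n_draws)
        delay_fits: dict[str, object] = {}
        rows = []
        for i, j in enumerate(jurisdictions):
            if cfg.nowcast_delay_model == "nonparametric":
                fit = inf.fit_nonparametric(series, j, seed=seed + i, **mcmc)
                point = fit.point()
                mean, sd = point.mean_delay(), float("nan")
            else:
                fit = inf.fit_independent(
                    series, j, cfg.nowcast_delay_model, seed=seed + i, **mcmc
                )
                point = fit.point()
                mean, sd = point.mean, point.sd
            delay_fits[j] = fit
            rows.append({
                "jurisdiction": j, "model": cfg.nowcast_delay_model,
                "mean_delay_weeks": mean, "sd_weeks": sd,
                "fraction_within_10_days": point.fraction_within_10_days(),
                "max_rhat": fit.max_rhat,
            })
        delay_df = pd.DataFrame(rows)
        delay_df.to_csv(out / "delay_fits.csv", index=False)
        record("delay_fits", {"delay_fits": "delay_fits.csv"},
               model=cfg.nowcast_delay_model, seed=seed)

        # ---- stage: partial pool + outliers -----------------------------
        seed = _subseed(cfg.seed, "pool")
        report = inf.outlier_scan(
            series, threshold=cfg.outlier_threshold, seed=seed, **mcmc
        )
        pool = inf.fit_partial_pool(
            series, excluded=report.flagged_set, seed=seed + 99, **mcmc
        )
        pool.summary().to_csv(out / "pool_summary.csv", index=False)
        pd.DataFrame({
            "jurisdiction": report.pvalues.index,
            "median_pvalue": report.pvalues.to_numpy(),
            "flagged": [j in report.flagged_set for j in report.pvalues.index],
        }).to_csv(out / "outliers.csv", index=False)
        record("pool_outliers",
               {"pool_summary": "pool_summary.csv", "outliers": "outliers.csv"},
               flagged=report.flagged, seed=seed, max_rhat=pool.max_rhat,
               mu_median=float(np.median(pool.mu)))

        # ---- stage: nowcast ---------------------------------------------
        seed = _subseed(cfg.seed, "nowcast")
        nc = ncmod.nowcast_series(series, delay_fits, n_draws=cfg.nowcast_draws, seed=seed)
        nc.table.to_csv(out / "nowcast.csv", index=False)
        record("nowcast", {"nowcast": "nowcast.csv"}, seed=seed)

        # ---- stage: baseline + excess -----------------------------------
        seed = _subseed(cfg.seed, "baseline")
        excess_rows = []
        for i, j in enumerate(jurisdictions):
            bp = bl.fit_baseline(historical, j, seed=seed + i)
            weekly = bl.excess_by_week(nc, bp)
            for name, lo, hi in cfg.periods:
                s = bl.summarize_period(weekly, (lo, hi))
                excess_rows.append({
                    "jurisdiction": j, "period": name,
                    "excess_low": s.excess_low, "excess_high": s.excess_high,
                    "percent_low": s.percent_low, "percent_high": s.percent_high,
                    "expected_deaths": s.expected_deaths,
                })
        excess_df = pd.DataFrame(excess_rows)
        excess_df.to_csv(out / "excess.csv", index=False)
        record("excess", {"excess": "excess.csv"}, seed=seed)

        # ---- stage: covariate regression --------------------------------
        if covariates is not None:
            seed = _subseed(cfg.seed, "regression")
            cov = covariates.set_index("jurisdiction")
            x = cov.loc[jurisdictions, "covid_deaths_per_100k"].to_numpy(dtype=float)
            y = delay_df.set_index("jurisdiction").loc[
                jurisdictions, "mean_delay_weeks"
            ].to_numpy(dtype=float)
            fit_alt = reg.fit_robust_line(x, y, "slope", seed=seed)
            fit_null = reg.fit_robust_line(x, y, "null", seed=seed + 1)
            cmp = reg.compare_loo(fit_alt, fit_null, seed=seed + 2)
            summary = {
                "slope_weeks_per_unit": fit_alt.slope_median(),
                "slope_interval95": fit_alt.slope_interval(),
                "weekly_rate_units_per_week_of_delay": 1.0 / fit_alt.weekly_slope_median(),
                "delta_looic": cmp.delta_looic,
                "weight_alt": cmp.weights["alt"],
                "weight_null": cmp.weights["null"],
                "pareto_k_high": cmp.pareto_k_high,
            }
            (out / "regression.json").write_text(json.dumps(summary, indent=2))
            record("regression", {"regression": "regression.json"}, seed=seed)
    except Exception as exc:  # halt with the stage name in the log
        done = list(manifest["stages"])
        log.error("pipeline halted after stages %s: %s", done, exc)
        raise

    return out
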