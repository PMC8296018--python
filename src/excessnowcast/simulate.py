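"""Ground-truthed synthetic snapshot worlds.

The generator inverts the analysis' own assumptions so that every
downstream stage has a parameter-recovery target:

* weekly deaths per jurisdiction ~ Poisson(exp(intercept + trend t +
  seasonal harmonics)), plus an additive Poisson pandemic-excess component
  during 2020;
* each death receives an independent reporting delay from its
  jurisdiction's delay distribution; jurisdiction delay means scatter
  around a shared value with Student's-t deviations, with optional planted
  outliers;
* Wednesday-dated snapshots accumulate the deaths whose delay has elapsed
  by each publication date, with the CDC's <10 masking convention;
* a covariate table ties COVID-19 death burden to the delay means.

Defaults mirror the provisional-mortality setting: 53 jurisdictions, 21
Wednesday snapshots from late September 2020 to mid-February 2021, a
shared lognormal delay mean of 2.8 weeks with scale 0.7 weeks, and
historical baseline years 2014-2019.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ParametricDelay
from .mmwr import (
    JURISDICTIONS,
    HistoricalSeries,
    MMWRWeek,
    Snapshot,
    SnapshotSeries,
    elapsed_reporting_time,
    mmwr_weeks_in_year,
    week_ending_date,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_snapshot_dates",
    "simulate_true_deaths",
    "draw_jurisdiction_means",
    "simulate_snapshots",
    "simulate_covariates",
    "simulate_dataset",
]

#: 18 MMWR weeks in September--December 2020 (weeks 36-53): converts the
#: weekly covariate scale to the cumulative scale used in the covariate table
WEEKS_SEP_DEC = 18


def default_snapshot_dates(n: int = 21, last: dt.date = dt.date(2021, 2, 10)) -> list[dt.date]:
    """``n`` consecutive Wednesdays ending at ``last`` (default mirrors a
    late-September 2020 through mid-February 2021 collection window)."""
    if last.weekday() != 2:
        raise ValueError("last snapshot date must be a Wednesday")
    return [last - dt.timedelta(weeks=n - 1 - k) for k in range(n)]


@dataclass(frozen=True)
class SimulationConfig:
    """The stated synthetic world.  All rates are weekly; delays in weeks."""

    n_jurisdictions: int = 53
    # baseline log-rate: per-jurisdiction intercepts (log weekly deaths),
    # shared secular trend (per week) and two annual harmonics
    intercepts: tuple[float, ...] | None = None   # default: log-spaced 150..3000
    trend_per_week: float = 3e-4
    harmonic_amplitudes: tuple[float, float] = (0.10, 0.03)
    harmonic_phases: tuple[float, float] = (0.15, 0.4)  # radians; winter peak
    # pandemic excess: Gaussian waves in 2020, magnitudes relative to baseline
    excess_waves: tuple[tuple[float, float, float], ...] = (
        (15.0, 4.0, 0.35),   # (peak MMWR week, width in weeks, relative magnitude)
        (47.0, 5.0, 0.25),
    )
    excess_multiplier: float = 1.0  # global scaling of the excess component
    # reporting delays
    mu_true: float = 2.8            # shared mean delay (weeks)
    sigma_mu_true: float = 0.7      # scale of between-jurisdiction deviations
    nu_true: float = 4.0            # Student's-t dof of the deviations
    delay_family: str = "lognormal"
    delay_sd: float = 1.5           # per-jurisdiction delay sd (weeks)
    outliers: tuple[tuple[str, float], ...] = ()  # (jurisdiction, inflated mean)
    # covariate model: mean delay = intercept + slope * (cumulative COVID
    # deaths per 100k, Sep-Dec) + Student-t noise
    covariate_intercept: float = 1.0
    covariate_slope: float = 1.0 / (4.5 * WEEKS_SEP_DEC)
    covariate_noise: float = 0.3
    covariate_nu: float = 4.0
    # snapshots
    snapshot_dates: tuple[dt.date, ...] = tuple(default_snapshot_dates())
    snapshot_first_week: tuple[int, int] = (2020, 10)
    masking: bool = True
    # historical baseline
    historical_years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018, 2019)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_true > 0 and self.sigma_mu_true > 0 and self.nu_true > 0):
            raise ValueError("delay hyperparameters must be positive")
        if self.intercepts is None:
            vals = np.linspace(np.log(150.0), np.log(3000.0), self.n_jurisdictions)
            object.__setattr__(self, "intercepts", tuple(vals))
        if len(self.intercepts) != self.n_jurisdictions:
            raise ValueError("one intercept per jurisdiction required")
        dates = list(self.snapshot_dates)
        if any(d.weekday() != 2 for d in dates):
            raise ValueError("snapshot dates must be Wednesdays")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("snapshot dates must strictly increase")

    @property
    def jurisdictions(self) -> tuple[str, ...]:
        return JURISDICTIONS[: self.n_jurisdictions]


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_counts: pd.DataFrame       # jurisdiction, mmwr_year, mmwr_week, deaths,
                                    # baseline_rate, excess_rate, excess_deaths
    delay_params: pd.DataFrame      # jurisdiction, family, mean, sd, is_outlier
    config: SimulationConfig

    def delay_for(self, jurisdiction: str) -> ParametricDelay:
        row = self.delay_params.set_index("jurisdiction").loc[jurisdiction]
        return ParametricDelay(row["family"], float(row["mean"]), float(row["sd"]))

    def final_counts(self, year: int = 2020) -> pd.DataFrame:
        df = self.true_counts
        return df[df["mmwr_year"] == year]


@dataclass
class SyntheticDataset:
    series: SnapshotSeries
    historical: HistoricalSeries
    covariates: pd.DataFrame
    truth: GroundTruth


def _year_fraction(week: MMWRWeek) -> float:
    end = week_ending_date(week)
    return (end.timetuple().tm_yday - 3.5) / 365.25


def _log_baseline_rate(cfg: SimulationConfig, intercept: float, week: MMWRWeek,
                       t_weeks: float) -> float:
    frac = _year_fraction(week)
    seasonal = sum(
        a * np.cos(2 * np.pi * (k + 1) * frac - p)
        for k, (a, p) in enumerate(zip(cfg.harmonic_amplitudes, cfg.harmonic_phases))
    )
    return intercept + cfg.trend_per_week * t_weeks + seasonal


def _excess_rate(cfg: SimulationConfig, baseline_rate: float, week: MMWRWeek) -> float:
    if week.year != 2020:
        return 0.0
    rel = sum(
        mag * np.exp(-0.5 * ((week.week - peak) / width) ** 2)
        for peak, width, mag in cfg.excess_waves
    )
    return baseline_rate * rel * cfg.excess_multiplier


def simulate_true_deaths(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw true weekly deaths for the historical years and 2020.

    Weekly counts are Poisson with a log-linear seasonal baseline; 2020
    weeks add an independent Poisson excess component (additive waves).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    years = list(config.historical_years) + [2020]
    origin = week_ending_date(MMWRWeek(years[0], 1))
    rows = []
    for j, intercept in zip(config.jurisdictions, config.intercepts):
        for year in years:
            for w in range(1, mmwr_weeks_in_year(year) + 1):
                week = MMWRWeek(year, w)
                t_weeks = (week_ending_date(week) - origin).days / 7.0
                log_rate = _log_baseline_rate(config, intercept, week, t_weeks)
                if log_rate > 30:
                    raise OverflowError("baseline rate overflow")
                base_rate = np.exp(log_rate)
                exc_rate = _excess_rate(config, base_rate, week)
                base_deaths = rng.poisson(base_rate)
                exc_deaths = rng.poisson(exc_rate) if exc_rate > 0 else 0
                rows.append(
                    (j, year, w, base_deaths + exc_deaths, base_rate, exc_rate, exc_deaths)
                )
    df = pd.DataFrame(
        rows,
        columns=["jurisdiction", "mmwr_year", "mmwr_week", "deaths",
                 "baseline_rate", "excess_rate", "excess_deaths"],
    )
    delays = _delay_table(config, rng)
    return GroundTruth(true_counts=df, delay_params=delays, config=config)


def draw_jurisdiction_means(
    mu_true: float,
    sigma_mu_true: float,
    nu_true: float,
    n: int,
    rng: np.random.Generator,
    outliers: dict[int, float] | None = None,
    floor: float = 0.1,
) -> np.ndarray:
    """Per-jurisdiction delay means: Student-t(nu, mu, sigma) draws truncated
    below at ``floor`` weeks, with planted outliers overwritten."""
    means = np.empty(n)
    for k in range(n):
        val = mu_true + sigma_mu_true * rng.standard_t(nu_true)
        while val <= floor:
            val = mu_true + sigma_mu_true * rng.standard_t(nu_true)
        means[k] = val
    if outliers:
        for idx, val in outliers.items():
            means[idx] = val
    return means


def _delay_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    jurs = config.jurisdictions
    unknown = [j for j, _ in config.outliers if j not in jurs]
    if unknown:
        raise ValueError(f"outlier jurisdictions not in the registry slice: {unknown}")
    out_idx = {jurs.index(j): m for j, m in config.outliers}
    means = draw_jurisdiction_means(
        config.mu_true, config.sigma_mu_true, config.nu_true, len(jurs), rng, out_idx
    )
    return pd.DataFrame({
        "jurisdiction": jurs,
        "family": config.delay_family,
        "mean": means,
        "sd": config.delay_sd,
        "is_outlier": [k in out_idx for k in range(len(jurs))],
    })


def simulate_snapshots(
    truth: GroundTruth,
    snapshot_dates: list[dt.date] | None = None,
    masking: bool | None = None,
    rng: np.random.Generator | None = None,
) -> SnapshotSeries:
    """Thin the true 2020 deaths into publication-dated snapshots.

    Each death receives an independent delay, realised as a multinomial
    split of the weekly count over the CDF increments between successive
    publication dates; snapshot s holds the deaths whose delay had elapsed
    by its publication date.  Counts in 1..9 are masked when enabled.
    """
    cfg = truth.config
    dates = list(snapshot_dates if snapshot_dates is not None else cfg.snapshot_dates)
    if masking is None:
        masking = cfg.masking
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    first_week = MMWRWeek(*cfg.snapshot_first_week)
    final = truth.final_counts()
    delays = {j: truth.delay_for(j) for j in cfg.jurisdictions}

    per_snapshot_rows: list[list] = [[] for _ in dates]
    for _, row in final.iterrows():
        week = MMWRWeek(int(row["mmwr_year"]), int(row["mmwr_week"]))
        if week_ending_date(week) < week_ending_date(first_week):
            continue
        j = row["jurisdiction"]
        n = int(row["deaths"])
        elapsed = np.array([elapsed_reporting_time(d, week) for d in dates])
        F = np.asarray(delays[j].cdf(elapsed))
        F = np.maximum.accumulate(np.clip(F, 0.0, 1.0))
        probs = np.diff(np.concatenate([[0.0], F, [1.0]]))
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        split = rng.multinomial(n, probs)
        cum = np.cumsum(split)[:-1]  # reported count by each snapshot
        for s, date in enumerate(dates):
            if elapsed[s] <= 0:
                continue
            per_snapshot_rows[s].append((j, week.year, week.week, int(cum[s])))

    snaps = []
    for date, rows in zip(dates, per_snapshot_rows):
        df = pd.DataFrame(rows, columns=["jurisdiction", "mmwr_year", "mmwr_week", "deaths"])
        df["deaths"] = df["deaths"].astype(float)
        df["masked"] = False
        if masking:
            hide = df["deaths"].between(1, 9)
            df.loc[hide, "masked"] = True
            df.loc[hide, "deaths"] = np.nan
        snaps.append(Snapshot(date, df, registry=cfg.jurisdictions))
    return SnapshotSeries(snaps)


def simulate_covariates(
    delay_means: pd.Series,
    slope: float,
    noise_scale: float,
    intercept: float = 1.0,
    nu: float = 4.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """COVID-19 deaths per 100 000 consistent with the configured
    delay-vs-burden line: mean_delay = intercept + slope * x + t-noise.

    With ``noise_scale`` = 0 the line is exact.  Jurisdictions whose delay
    mean sits below the intercept get a clipped-at-zero burden.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    noise = noise_scale * rng.standard_t(nu, size=len(delay_means)) if noise_scale > 0 \
        else np.zeros(len(delay_means))
    x = (delay_means.to_numpy() - intercept - noise) / slope
    x = np.clip(x, 0.0, None)
    return pd.DataFrame({
        "jurisdiction": delay_means.index,
        "covid_deaths_per_100k": x,
        "mean_delay_weeks": delay_means.to_numpy(),
    })


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full bundle: snapshot series, historical baseline table, covariates
    and ground truth, all reproducible from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    truth = simulate_true_deaths(config, rng)
    series = simulate_snapshots(truth, rng=rng)
    hist_df = truth.true_counts[
        truth.true_counts["mmwr_year"].isin(config.historical_years)
    ][["jurisdiction", "mmwr_year", "mmwr_week", "deaths"]].copy()
    hist_df["deaths"] = hist_df["deaths"].astype(float)
    hist_df["masked"] = False
    hist_df["source_year"] = hist_df["mmwr_year"]
    historical = HistoricalSeries(hist_df, registry=config.jurisdictions)
    means = truth.delay_params.set_index("jurisdiction")["mean"]
    covariates = simulate_covariates(
        means, config.covariate_slope, config.covariate_noise,
        config.covariate_intercept, config.covariate_nu, rng,
    )
    return SyntheticDataset(series, historical, covariates, truth)
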