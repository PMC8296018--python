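"""Seasonal mortality baseline and excess-death summaries.

Expected weekly deaths are modelled with a Bayesian Poisson regression on
a log link: intercept, linear secular trend in continuous time, and two
annual harmonics (sin/cos of 2 pi k t / 52.1775 weeks, k = 1, 2), trained
on complete historical years and projected onto the weeks of 2020.  Two
thresholds per week — the posterior median and the 95th percentile of the
expected count — convert a nowcast into a per-week excess range
(differences truncated at zero), summed over reporting periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mcmc import ScaleAdapter, split_rhat
from .mmwr import HistoricalSeries, MMWRWeek, mmwr_weeks_in_year, week_ending_date
from .nowcast import NowcastResult

__all__ = [
    "WEEKS_IN_YEAR",
    "PERIOD_MAR_DEC",
    "PERIOD_SEP_DEC",
    "BaselinePosterior",
    "ExcessSummary",
    "fit_baseline",
    "excess_by_week",
    "summarize_period",
]

WEEKS_IN_YEAR = 52.1775  # mean tropical year in weeks; harmonic period

# period boundaries in MMWR weeks of 2020 (inclusive)
PERIOD_MAR_DEC = (10, 53)   # March--December
PERIOD_SEP_DEC = (36, 53)   # September--December


def _design(t_weeks: np.ndarray, harmonics: int) -> np.ndarray:
    cols = [np.ones_like(t_weeks), t_weeks]
    for k in range(1, harmonics + 1):
        ang = 2 * np.pi * k * t_weeks / WEEKS_IN_YEAR
        cols += [np.sin(ang), np.cos(ang)]
    return np.column_stack(cols)


@dataclass
class BaselinePosterior:
    """Posterior draws of expected weekly deaths for the weeks of 2020."""

    jurisdiction: str
    weeks: list[MMWRWeek]
    rate_draws: np.ndarray      # (n_draws, n_weeks)
    coef_draws: np.ndarray      # (n_draws, n_coef)
    max_rhat: float

    def thresholds(self) -> pd.DataFrame:
        """Per-week posterior median and 95th percentile of expected deaths."""
        med = np.median(self.rate_draws, axis=0)
        q95 = np.quantile(self.rate_draws, 0.95, axis=0)
        return pd.DataFrame({
            "mmwr_year": [w.year for w in self.weeks],
            "mmwr_week": [w.week for w in self.weeks],
            "threshold_median": med,
            "threshold_q95": q95,
        })


def fit_baseline(
    historical: HistoricalSeries,
    jurisdiction: str,
    *,
    harmonics: int = 2,
    target_year: int = 2020,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 300,
    n_draws: int = 500,
) -> BaselinePosterior:
    """Fit the seasonal Poisson baseline for one jurisdiction.

    MCMC uses a multivariate random-walk proposal pre-scaled by the Laplace
    (GLM) covariance, so the six-dimensional posterior mixes in a few
    hundred iterations.  The target year is never part of training.
    """
    sub = historical.counts(jurisdiction)
    years = sorted(set(sub["mmwr_year"]) - {target_year})
    if len(years) < 3:
        raise ValueError("need at least 3 complete historical years")
    sub = sub[sub["mmwr_year"].isin(years)]
    origin = week_ending_date(MMWRWeek(years[0], 1))
    t = np.array([
        (week_ending_date(MMWRWeek(int(y), int(w))) - origin).days / 7.0
        for y, w in zip(sub["mmwr_year"], sub["mmwr_week"])
    ])
    y = sub["deaths"].to_numpy(dtype=float)
    X = _design(t, harmonics)

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(glm.params)
    L = np.linalg.cholesky(np.asarray(glm.cov_params()))

    def loglik(beta: np.ndarray) -> float:
        eta = X @ beta
        if np.any(eta > 30):
            return -np.inf
        lam = np.exp(eta)
        return float(np.sum(y * eta - lam))  # Poisson kernel; weak flat prior

    rng = np.random.default_rng(seed)
    dim = beta0.size
    chains = np.empty((n_chains, n_draws, dim))
    for c in range(n_chains):
        x = beta0 + L @ rng.standard_normal(dim)
        lp = loglik(x)
        adapter = ScaleAdapter(1.0, target=0.234)
        for it in range(n_warmup + n_draws):
            prop = x + adapter.scale * (L @ rng.standard_normal(dim))
            lp_prop = loglik(prop)
            acc = float(np.exp(min(0.0, lp_prop - lp))) if np.isfinite(lp_prop) else 0.0
            if rng.random() < acc:
                x, lp = prop, lp_prop
            if it < n_warmup:
                adapter.update(acc)
            else:
                chains[c, it - n_warmup] = x
    max_rhat = float(np.nanmax(split_rhat(chains)))

    weeks = [MMWRWeek(target_year, w) for w in range(1, mmwr_weeks_in_year(target_year) + 1)]
    t_new = np.array([(week_ending_date(w) - origin).days / 7.0 for w in weeks])
    X_new = _design(t_new, harmonics)
    flat = chains.reshape(-1, dim)
    rate_draws = np.exp(flat @ X_new.T)
    return BaselinePosterior(jurisdiction, weeks, rate_draws, flat, max_rhat)


def excess_by_week(nowcast: NowcastResult, baseline: BaselinePosterior) -> pd.DataFrame:
    """Per-week excess against the two thresholds.

    excess_high uses the (lower) median threshold, excess_low the 95th
    percentile threshold; negative differences are assigned to zero, so
    0 <= excess_low <= excess_high for every week.
    """
    thr = baseline.thresholds()
    nc = nowcast.table[nowcast.table["jurisdiction"] == baseline.jurisdiction]
    if nc.empty:
        raise ValueError(f"nowcast has no rows for {baseline.jurisdiction!r}")
    merged = nc.merge(thr, on=["mmwr_year", "mmwr_week"], how="inner")
    if merged.empty:
        raise ValueError("nowcast and baseline weeks do not overlap")
    merged["excess_high"] = np.maximum(
        0.0, merged["nowcast_median"] - merged["threshold_median"]
    )
    merged["excess_low"] = np.maximum(
        0.0, merged["nowcast_median"] - merged["threshold_q95"]
    )
    return merged


@dataclass
class ExcessSummary:
    """Period excess-death range for one jurisdiction.

    ``excess_low``/``excess_high`` are the summed weekly differences of the
    nowcast median against the 95th-percentile and median thresholds;
    percent values divide by the period sum of the posterior-median
    expected deaths (an explicit package convention).
    """

    jurisdiction: str
    period: tuple[int, int]
    excess_low: float
    excess_high: float
    percent_low: float
    percent_high: float
    expected_deaths: float


def summarize_period(
    weekly: pd.DataFrame,
    period: tuple[int, int] = PERIOD_MAR_DEC,
    jurisdiction: str | None = None,
) -> ExcessSummary:
    """Sum weekly excess over ``period`` (inclusive MMWR-week range of 2020)
    and express it as a percent of the expected deaths in the period."""
    lo_w, hi_w = period
    sel = weekly[(weekly["mmwr_week"] >= lo_w) & (weekly["mmwr_week"] <= hi_w)]
    if sel.empty:
        raise ValueError(f"no weeks in period {period}")
    if jurisdiction is None:
        jurisdiction = str(sel["jurisdiction"].iloc[0])
    expected = float(sel["threshold_median"].sum())
    ex_hi = float(sel["excess_high"].sum())
    ex_lo = float(sel["excess_low"].sum())
    return ExcessSummary(
        jurisdiction=jurisdiction,
        period=period,
        excess_low=ex_lo,
        excess_high=ex_hi,
        percent_low=100.0 * ex_lo / expected,
        percent_high=100.0 * ex_hi / expected,
        expected_deaths=expected,
    )
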