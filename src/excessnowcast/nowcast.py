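"""Nowcasting final death counts from the latest provisional snapshot.

The number of not-yet-reported deaths for a week with ``reported`` deaths
and delay CDF value F (elapsed time from the death week to the latest
publication) follows the failure-counting negative binomial: unreported ~
NB(size = reported, success probability = F), so the expected unreported
count is reported * (1 - F) / F.  Delay-parameter uncertainty propagates by
pairing one delay posterior draw with each nowcast draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import MASK_MIDPOINT, excluded_weeks
from .mmwr import MMWRWeek, SnapshotSeries, elapsed_reporting_time

__all__ = ["NowcastResult", "nowcast_week", "nowcast_series", "validate_at_cutoffs"]


def _cdf_draws(delay_like, elapsed: np.ndarray, n_draws: int) -> np.ndarray:
    """Delay CDF values, shape (n_draws, len(elapsed)).

    Accepts a plain delay object (fixed CDF) or a fit with posterior draws
    (``delay_at`` indexable); posterior draws are cycled deterministically.
    """
    if hasattr(delay_like, "cdf"):
        row = np.asarray(delay_like.cdf(elapsed), dtype=float)
        return np.broadcast_to(row, (n_draws, elapsed.size)).copy()
    if hasattr(delay_like, "delay_at"):
        return np.stack(
            [np.asarray(delay_like.delay_at(i).cdf(elapsed)) for i in range(n_draws)]
        )
    if hasattr(delay_like, "point"):  # HazardFit without delay_at
        flat = delay_like.hazard_draws.reshape(-1, delay_like.hazard_draws.shape[-1])
        from .distributions import DiscreteHazardDelay

        return np.stack([
            np.asarray(DiscreteHazardDelay(tuple(flat[i % len(flat)])).cdf(elapsed))
            for i in range(n_draws)
        ])
    raise TypeError(f"cannot interpret {type(delay_like)!r} as a delay")


def nowcast_week(
    reported: int,
    delay,
    elapsed: float,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Posterior draws of the final count for one week.

    ``delay`` may be a delay object or a posterior fit; each draw uses its
    own delay CDF value.  A week with zero reported deaths returns draws
    identically zero (the failure-counting NB is degenerate at size 0;
    such trailing weeks are excluded upstream anyway).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if reported < 0:
        raise ValueError("reported count must be non-negative")
    if reported == 0:
        return np.zeros(n_draws, dtype=int)
    F = _cdf_draws(delay, np.asarray([elapsed], dtype=float), n_draws)[:, 0]
    if np.any(F <= 0):
        raise ValueError("delay CDF is 0 at the elapsed time but deaths were reported")
    F = np.clip(F, None, 1.0)
    unreported = rng.negative_binomial(reported, F)
    return reported + unreported


@dataclass
class NowcastResult:
    """Per-(jurisdiction, week) nowcast draws and summaries.

    ``table`` columns: jurisdiction, mmwr_year, mmwr_week, reported,
    nowcast_median, lower95, upper95, flagged (masked reported count or
    zero-reported degenerate cell).
    """

    table: pd.DataFrame
    draws: dict[tuple[str, MMWRWeek], np.ndarray]

    def draws_for(self, jurisdiction: str, week: MMWRWeek) -> np.ndarray:
        return self.draws[(jurisdiction, MMWRWeek(*week))]


def nowcast_series(
    series: SnapshotSeries,
    delays: dict[str, object],
    n_draws: int = 1000,
    seed: int = 0,
    weeks: list[MMWRWeek] | None = None,
) -> NowcastResult:
    """Nowcast every eligible week of the latest snapshot.

    ``delays`` maps jurisdiction to a delay object or posterior fit.  The
    publication week and the week before it are excluded (their counts are
    systematically missing); masked reported counts are nowcast from the
    censoring-interval midpoint (5) and flagged.
    """
    rng = np.random.default_rng(seed)
    final = series.final
    drop = excluded_weeks(final)
    rows = []
    draws_out: dict[tuple[str, MMWRWeek], np.ndarray] = {}
    for j in sorted(delays):
        sub = final.counts(j)
        if sub.empty:
            raise ValueError(f"no delay-eligible data for {j!r}")
        wk_list, elapsed, reported, flagged = [], [], [], []
        for _, row in sub.iterrows():
            wk = MMWRWeek(int(row["mmwr_year"]), int(row["mmwr_week"]))
            if wk in drop or (weeks is not None and wk not in weeks):
                continue
            t = elapsed_reporting_time(final.publication_date, wk)
            if t <= 0:
                continue
            masked = bool(row["masked"])
            wk_list.append(wk)
            elapsed.append(t)
            reported.append(MASK_MIDPOINT if masked else float(row["deaths"]))
            flagged.append(masked)
        elapsed_arr = np.asarray(elapsed)
        F = np.clip(_cdf_draws(delays[j], elapsed_arr, n_draws), None, 1.0)
        for i, wk in enumerate(wk_list):
            r = int(reported[i])
            if r == 0:
                d = np.zeros(n_draws, dtype=int)
                flag = True
            else:
                Fi = F[:, i]
                if np.any(Fi <= 0):
                    raise ValueError(
                        f"delay CDF 0 with reported deaths for {j} {wk}"
                    )
                d = r + rng.negative_binomial(r, Fi)
                flag = flagged[i]
            draws_out[(j, wk)] = d
            lo, med, hi = np.quantile(d, [0.025, 0.5, 0.975])
            rows.append((j, wk.year, wk.week, r, med, lo, hi, flag))
    table = pd.DataFrame(
        rows,
        columns=["jurisdiction", "mmwr_year", "mmwr_week", "reported",
                 "nowcast_median", "lower95", "upper95", "flagged"],
    )
    return NowcastResult(table=table, draws=draws_out)


def validate_at_cutoffs(
    series: SnapshotSeries,
    cutoff_dates,
    fit_strategy,
    jurisdictions: list[str] | None = None,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrospective nowcast validation at earlier cutoffs.

    For each cutoff date (a snapshot publication date), delays are refit
    using only the snapshots up to the cutoff via ``fit_strategy(subseries,
    jurisdiction)``; the resulting nowcasts are scored against the final
    snapshot: 95%-interval coverage, median relative error of the nowcast
    median, and the sign of the median bias.
    """
    if jurisdictions is None:
        jurisdictions = series.jurisdictions
    final_ref = {
        (r["jurisdiction"], MMWRWeek(int(r["mmwr_year"]), int(r["mmwr_week"]))): r["deaths"]
        for _, r in series.final.data.iterrows()
        if not r["masked"]
    }
    rows = []
    all_dates = [s.publication_date for s in series.snapshots]
    for cutoff in cutoff_dates:
        if cutoff not in all_dates:
            raise ValueError(f"cutoff {cutoff} is not a snapshot date")
        upto = all_dates.index(cutoff)
        if upto < 1:
            raise ValueError("cutoff before the second snapshot")
        sub = SnapshotSeries(series.snapshots[: upto + 1])
        delays = {j: fit_strategy(sub, j) for j in jurisdictions}
        nc = nowcast_series(sub, delays, n_draws=n_draws, seed=seed)
        errs, covered, n_scored = [], 0, 0
        for _, r in nc.table.iterrows():
            key = (r["jurisdiction"], MMWRWeek(int(r["mmwr_year"]), int(r["mmwr_week"])))
            truth = final_ref.get(key)
            if truth is None or truth <= 0 or r["flagged"]:
                continue
            n_scored += 1
            covered += int(r["lower95"] <= truth <= r["upper95"])
            errs.append((r["nowcast_median"] - truth) / truth)
        errs = np.asarray(errs)
        rows.append({
            "cutoff": cutoff,
            "n_cells": n_scored,
            "coverage95": covered / n_scored if n_scored else np.nan,
            "median_rel_error": float(np.median(errs)) if errs.size else np.nan,
            "bias_sign": int(np.sign(np.median(errs))) if errs.size else 0,
        })
    return pd.DataFrame(rows)
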