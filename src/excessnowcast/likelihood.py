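"""Poisson snapshot likelihood for reporting-delay inference.

Each provisional snapshot s < S reports, for week w and jurisdiction j, a
partial death count d(j,w,s).  Treating the latest snapshot S as complete,
the expected partial count is d(j,w,S) * F(t) where F is the reporting-delay
CDF and t the elapsed time from the mid-point of week w to the publication
date of snapshot s (the continuity correction).  Partial counts are Poisson
distributed around that expectation; privacy-masked cells (true count in
1..9) enter as interval-censored observations.

The publication week and the preceding week of every snapshot are excluded:
their counts are systematically missed in the release cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .mmwr import (
    MMWRWeek,
    Snapshot,
    SnapshotSeries,
    date_to_mmwr_week,
    elapsed_reporting_time,
)

__all__ = [
    "CellData",
    "MASK_LOW",
    "MASK_HIGH",
    "MASK_MIDPOINT",
    "prepare_cells",
    "poisson_loglik_cells",
    "expected_partial_count",
    "snapshot_loglik",
    "excluded_weeks",
]

# privacy masking replaces true counts in 1..9; midpoint used where a point
# value is unavoidable (masked *final* counts)
MASK_LOW, MASK_HIGH = 1, 9
MASK_MIDPOINT = 5.0
_MASK_KS = np.arange(MASK_LOW, MASK_HIGH + 1)


def excluded_weeks(snapshot: Snapshot) -> set[MMWRWeek]:
    """The snapshot's publication week and the week before it."""
    pub = date_to_mmwr_week(snapshot.publication_date)
    return {pub, pub - 1}


@dataclass
class CellData:
    """Flattened eligible (snapshot, week) cells for one jurisdiction.

    ``obs`` is NaN where the partial count is masked; ``final`` uses the
    censoring-interval midpoint for masked final counts (``final_masked``
    records where).
    """

    jurisdiction: str
    obs: np.ndarray
    obs_masked: np.ndarray
    final: np.ndarray
    final_masked: np.ndarray
    elapsed: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.obs.size

    @property
    def degenerate(self) -> bool:
        """True when every partial count already equals its final count, so
        the data carry no delay information (all weeks fully reported)."""
        ok = ~(self.obs_masked | self.final_masked)
        return bool(np.all(self.obs[ok] == self.final[ok]))


def prepare_cells(series: SnapshotSeries, jurisdiction: str) -> CellData:
    """Extract the likelihood's raw material for one jurisdiction."""
    if len(series) < 2:
        raise ValueError("need at least two snapshots")
    final_snap = series.final
    fdf = final_snap.counts(jurisdiction)
    if fdf.empty:
        raise ValueError(f"jurisdiction {jurisdiction!r} not in final snapshot")
    drop_final = excluded_weeks(final_snap)
    finals: dict[MMWRWeek, tuple[float, bool]] = {}
    for _, row in fdf.iterrows():
        wk = MMWRWeek(int(row["mmwr_year"]), int(row["mmwr_week"]))
        if wk in drop_final:
            continue
        if row["masked"]:
            finals[wk] = (MASK_MIDPOINT, True)
        else:
            finals[wk] = (float(row["deaths"]), False)

    obs, obs_masked, final, final_masked, elapsed = [], [], [], [], []
    for snap in series.snapshots[:-1]:
        drop = excluded_weeks(snap)
        sdf = snap.counts(jurisdiction)
        for _, row in sdf.iterrows():
            wk = MMWRWeek(int(row["mmwr_year"]), int(row["mmwr_week"]))
            if wk in drop or wk not in finals:
                continue
            t = elapsed_reporting_time(snap.publication_date, wk)
            if t <= 0:
                continue
            f_count, f_masked = finals[wk]
            obs.append(np.nan if row["masked"] else float(row["deaths"]))
            obs_masked.append(bool(row["masked"]))
            final.append(f_count)
            final_masked.append(f_masked)
            elapsed.append(t)
    if not obs:
        raise ValueError(f"no eligible cells for {jurisdiction!r}")
    return CellData(
        jurisdiction=jurisdiction,
        obs=np.asarray(obs),
        obs_masked=np.asarray(obs_masked, dtype=bool),
        final=np.asarray(final),
        final_masked=np.asarray(final_masked, dtype=bool),
        elapsed=np.asarray(elapsed),
    )


def poisson_loglik_cells(cells: CellData, F: np.ndarray) -> float:
    """Log-likelihood of the partial counts given delay CDF values ``F``
    (one per cell, aligned with ``cells.elapsed``).

    Unmasked cells contribute the Poisson log-pmf; masked cells contribute
    the log of the pmf summed over the censoring interval 1..9.
    """
    E = cells.final * F
    ll = 0.0
    um = ~cells.obs_masked
    if um.any():
        y, mu = cells.obs[um], E[um]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                mu > 0,
                y * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(y + 1),
                np.where(y == 0, 0.0, -np.inf),
            )
        ll += float(terms.sum())
    if cells.obs_masked.any():
        mu = E[cells.obs_masked][:, None]
        with np.errstate(divide="ignore"):
            logpmf = _MASK_KS * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(_MASK_KS + 1)
            logpmf = np.where(mu > 0, logpmf, -np.inf)
        ll += float(logsumexp(logpmf, axis=1).sum())
    return ll


def expected_partial_count(final_count: float, delay, elapsed: float) -> float:
    """final_count * F(elapsed); zero when no reporting time has elapsed."""
    if final_count < 0:
        raise ValueError("final_count must be non-negative")
    if elapsed <= 0:
        return 0.0
    return float(final_count * delay.cdf(elapsed))


def snapshot_loglik(series: SnapshotSeries, delay, jurisdiction: str) -> float:
    """Total Poisson snapshot log-likelihood for one jurisdiction and one
    delay model (any object with the ``cdf`` contract)."""
    cells = prepare_cells(series, jurisdiction)
    return poisson_loglik_cells(cells, np.asarray(delay.cdf(cells.elapsed)))
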