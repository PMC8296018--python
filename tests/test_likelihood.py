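"""Poisson snapshot likelihood: exact values against brute-force oracles."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy import stats

from excessnowcast.distributions import ParametricDelay
from excessnowcast.likelihood import (
    CellData,
    excluded_weeks,
    expected_partial_count,
    poisson_loglik_cells,
    prepare_cells,
    snapshot_loglik,
)
from excessnowcast.mmwr import MMWRWeek, date_to_mmwr_week, elapsed_reporting_time

from conftest import make_snapshot


class TestExpectedPartialCount:
    def test_proportionality(self):
        class Half:
            def cdf(self, t):
                return np.asarray(0.5)

        assert expected_partial_count(100, Half(), 2.0) == pytest.approx(50.0)

    def test_empty_week(self):
        d = ParametricDelay("lognormal", 2.8, 1.5)
        assert expected_partial_count(0, d, 3.0) == 0.0

    def test_zero_for_nonpositive_elapsed(self):
        d = ParametricDelay("lognormal", 2.8, 1.5)
        assert expected_partial_count(100, d, -1.0) == 0.0
        assert expected_partial_count(100, d, 0.0) == 0.0

    def test_lognormal_quadrature_oracle(self):
        from scipy import integrate

        d = ParametricDelay("lognormal", 2.8, 2.8)
        q, _ = integrate.quad(d.dist.pdf, 0, 2.8)
        assert expected_partial_count(100, d, 2.8) == pytest.approx(100 * q, abs=1e-6)


def _single_cell(obs, masked, final, elapsed=2.0):
    return CellData(
        jurisdiction="X",
        obs=np.array([np.nan if masked else float(obs)]),
        obs_masked=np.array([masked]),
        final=np.array([float(final)]),
        final_masked=np.array([False]),
        elapsed=np.array([elapsed]),
    )


class TestPoissonLoglik:
    def test_single_cell_direct_formula(self):
        cells = _single_cell(5, False, 10)
        ll = poisson_loglik_cells(cells, np.array([0.5]))  # expected = 5
        assert ll == pytest.approx(stats.poisson.logpmf(5, 5.0))

    def test_masked_cell_nine_term_sum(self):
        cells = _single_cell(None, True, 8)
        ll = poisson_loglik_cells(cells, np.array([0.5]))  # expected = 4
        oracle = np.log(sum(stats.poisson.pmf(k, 4.0) for k in range(1, 10)))
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_zero_expected_zero_observed(self):
        cells = _single_cell(0, False, 10)
        assert poisson_loglik_cells(cells, np.array([0.0])) == 0.0

    def test_zero_expected_positive_observed_impossible(self):
        cells = _single_cell(3, False, 10)
        assert poisson_loglik_cells(cells, np.array([0.0])) == -np.inf


class TestSnapshotLoglik:
    def test_brute_force_oracle(self, toy_series):
        """Grid over (mean, sd): library likelihood equals an independent
        re-derivation looping snapshots and weeks with scipy Poisson pmfs."""

        def brute(delay, jurisdiction):
            final = toy_series.final
            finals = {
                MMWRWeek(int(r["mmwr_year"]), int(r["mmwr_week"])): float(r["deaths"])
                for _, r in final.counts(jurisdiction).iterrows()
            }
            total = 0.0
            for snap in toy_series.snapshots[:-1]:
                drop = excluded_weeks(snap)
                for _, r in snap.counts(jurisdiction).iterrows():
                    wk = MMWRWeek(int(r["mmwr_year"]), int(r["mmwr_week"]))
                    if wk in drop or wk not in finals:
                        continue
                    t = elapsed_reporting_time(snap.publication_date, wk)
                    if t <= 0:
                        continue
                    E = finals[wk] * float(delay.cdf(t))
                    if bool(r["masked"]):
                        total += np.log(
                            sum(stats.poisson.pmf(k, E) for k in range(1, 10))
                        )
                    else:
                        total += stats.poisson.logpmf(int(r["deaths"]), E)
            return total

        for mean, sd, j in itertools.product(
            [1.5, 2.8, 5.0], [1.0, 2.5], ["Alabama", "Alaska"]
        ):
            delay = ParametricDelay("lognormal", mean, sd)
            assert snapshot_loglik(toy_series, delay, j) == pytest.approx(
                brute(delay, j), abs=1e-9
            )

    def test_row_order_invariance(self, toy_series):
        d = ParametricDelay("lognormal", 2.8, 1.5)
        base = snapshot_loglik(toy_series, d, "Alabama")
        shuffled = toy_series
        # permute the rows of every snapshot table
        import excessnowcast.mmwr as mmwr

        snaps = []
        for s in toy_series.snapshots:
            snaps.append(
                mmwr.Snapshot(s.publication_date,
                              s.data.sample(frac=1, random_state=0),
                              registry=s.registry)
            )
        assert snapshot_loglik(mmwr.SnapshotSeries(snaps), d, "Alabama") == \
            pytest.approx(base, abs=1e-12)

    def test_recent_two_weeks_excluded(self):
        # a snapshot published during week 44 must not use weeks 43 and 44
        snap1 = make_snapshot(
            dt.date(2020, 10, 28),  # MMWR week 44
            [("Alabama", 2020, 42, 10), ("Alabama", 2020, 43, 5),
             ("Alabama", 2020, 44, 1)],
        )
        snap2 = make_snapshot(
            dt.date(2021, 6, 2),
            [("Alabama", 2020, 42, 20), ("Alabama", 2020, 43, 20),
             ("Alabama", 2020, 44, 20)],
        )
        from excessnowcast.mmwr import SnapshotSeries

        cells = prepare_cells(SnapshotSeries([snap1, snap2]), "Alabama")
        assert cells.n_cells == 1  # only week 42 survives
        assert cells.obs[0] == 10

    def test_pub_week_set(self):
        snap = make_snapshot(dt.date(2020, 10, 28), [("Alabama", 2020, 40, 1)])
        assert excluded_weeks(snap) == {MMWRWeek(2020, 44), MMWRWeek(2020, 43)}
        assert date_to_mmwr_week(dt.date(2020, 10, 28)) == MMWRWeek(2020, 44)
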