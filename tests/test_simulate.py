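"""Generator contracts: determinism, conservation, delay thinning, limits."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from excessnowcast.distributions import ParametricDelay
from excessnowcast.mmwr import MMWRWeek, elapsed_reporting_time
from excessnowcast.simulate import (
    SimulationConfig,
    default_snapshot_dates,
    draw_jurisdiction_means,
    simulate_covariates,
    simulate_dataset,
    simulate_snapshots,
    simulate_true_deaths,
)


def _flat_config(**kw):
    """One jurisdiction, constant rate, no excess unless overridden."""
    defaults = dict(
        n_jurisdictions=1, intercepts=(np.log(100.0),), trend_per_week=0.0,
        harmonic_amplitudes=(0.0, 0.0), excess_multiplier=0.0,
        historical_years=(2016, 2017, 2018, 2019), masking=False, rng_seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestTrueDeaths:
    def test_constant_rate_long_run_mean(self):
        truth = simulate_true_deaths(_flat_config())
        counts = truth.true_counts["deaths"]
        # ~260 Poisson(100) weeks: mean within 4 standard errors
        assert counts.mean() == pytest.approx(100, abs=4 * 10 / np.sqrt(len(counts)))

    def test_seed_determinism(self):
        a = simulate_true_deaths(_flat_config(rng_seed=5))
        b = simulate_true_deaths(_flat_config(rng_seed=5))
        pd.testing.assert_frame_equal(a.true_counts, b.true_counts)
        pd.testing.assert_frame_equal(a.delay_params, b.delay_params)

    def test_zero_excess_is_baseline_only(self):
        truth = simulate_true_deaths(_flat_config())
        assert (truth.true_counts["excess_deaths"] == 0).all()
        assert (truth.true_counts["excess_rate"] == 0).all()

    def test_excess_only_in_2020(self):
        truth = simulate_true_deaths(_flat_config(excess_multiplier=1.0))
        df = truth.true_counts
        assert (df.loc[df["mmwr_year"] != 2020, "excess_rate"] == 0).all()
        assert df.loc[df["mmwr_year"] == 2020, "excess_rate"].max() > 0


class TestSnapshots:
    def test_dataset_determinism(self):
        a = simulate_dataset(SimulationConfig(n_jurisdictions=3, rng_seed=4))
        b = simulate_dataset(SimulationConfig(n_jurisdictions=3, rng_seed=4))
        for sa, sb in zip(a.series.snapshots, b.series.snapshots):
            pd.testing.assert_frame_equal(sa.data, sb.data)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_counts_monotone_and_converge_to_truth(self):
        cfg = _flat_config()
        rng = np.random.default_rng(1)
        truth = simulate_true_deaths(cfg, rng)
        # final snapshot far beyond the last week + short delays: complete
        dates = default_snapshot_dates(12, last=dt.date(2021, 12, 29))
        truth.delay_params["mean"] = 1.0
        truth.delay_params["sd"] = 0.5
        series = simulate_snapshots(truth, dates, masking=False, rng=rng)
        final = truth.final_counts().set_index(["mmwr_year", "mmwr_week"])["deaths"]
        prev = None
        for snap in series.snapshots:
            cur = snap.data.set_index(["mmwr_year", "mmwr_week"])["deaths"]
            if prev is not None:
                joined = pd.concat({"a": prev, "b": cur}, axis=1).dropna()
                assert (joined["b"] >= joined["a"]).all()
            prev = cur
        last = series.final.data.set_index(["mmwr_year", "mmwr_week"])["deaths"]
        for key, val in last.items():
            assert val == final.loc[key]

    def test_degenerate_delay_reports_everything(self):
        cfg = _flat_config()
        rng = np.random.default_rng(2)
        truth = simulate_true_deaths(cfg, rng)
        truth.delay_params["mean"] = 0.01
        truth.delay_params["sd"] = 0.005
        series = simulate_snapshots(truth, masking=False, rng=rng)
        final = truth.final_counts().set_index(["mmwr_year", "mmwr_week"])["deaths"]
        first = series.snapshots[0]
        for _, r in first.data.iterrows():
            wk = MMWRWeek(int(r["mmwr_year"]), int(r["mmwr_week"]))
            t = elapsed_reporting_time(first.publication_date, wk)
            if t > 0.1:  # fully elapsed for a near-zero delay
                assert r["deaths"] == final.loc[(wk.year, wk.week)]

    def test_huge_delay_reports_nothing_early(self):
        cfg = _flat_config()
        rng = np.random.default_rng(3)
        truth = simulate_true_deaths(cfg, rng)
        truth.delay_params["mean"] = 200.0
        truth.delay_params["sd"] = 10.0
        series = simulate_snapshots(truth, masking=False, rng=rng)
        assert series.snapshots[0].data["deaths"].sum() == 0

    def test_reported_fraction_matches_cdf(self):
        """Monte-Carlo vs CDF oracle: with a large weekly count the reported
        fraction at each snapshot is the delay CDF at its elapsed time."""
        cfg = _flat_config(intercepts=(np.log(20000.0),),
                           snapshot_first_week=(2020, 40))
        rng = np.random.default_rng(4)
        truth = simulate_true_deaths(cfg, rng)
        truth.delay_params["mean"] = 2.8
        truth.delay_params["sd"] = 1.5
        series = simulate_snapshots(truth, masking=False, rng=rng)
        delay = ParametricDelay("lognormal", 2.8, 1.5)
        wk = MMWRWeek(2020, 44)
        n = truth.final_counts().set_index(["mmwr_year", "mmwr_week"])["deaths"].loc[
            (2020, 44)
        ]
        for snap in series.snapshots[:: 5]:
            t = elapsed_reporting_time(snap.publication_date, wk)
            if t <= 0:
                continue
            F = float(delay.cdf(t))
            row = snap.data[(snap.data.mmwr_week == 44) & (snap.data.mmwr_year == 2020)]
            frac = float(row["deaths"].iloc[0]) / n
            tol = 5 * np.sqrt(max(F * (1 - F), 1e-6) / n)
            assert frac == pytest.approx(F, abs=tol)

    def test_masking_applied_in_memory(self):
        cfg = _flat_config(intercepts=(np.log(15.0),), masking=True)
        ds = simulate_dataset(cfg)
        frames = pd.concat([s.data for s in ds.series.snapshots])
        assert frames["masked"].any()  # partial counts of a small jurisdiction
        assert frames.loc[frames["masked"], "deaths"].isna().all()
        unmasked = frames.loc[~frames["masked"], "deaths"].dropna()
        assert not unmasked.between(1, 9).any()


class TestJurisdictionMeans:
    def test_degenerate_scale(self):
        rng = np.random.default_rng(0)
        means = draw_jurisdiction_means(2.8, 1e-12, 4.0, 10, rng)
        np.testing.assert_allclose(means, 2.8, atol=1e-9)

    def test_planted_outlier_exact(self):
        rng = np.random.default_rng(0)
        means = draw_jurisdiction_means(2.8, 0.7, 4.0, 10, rng, outliers={3: 10.4})
        assert means[3] == 10.4

    def test_normal_limit_large_dof(self):
        rng = np.random.default_rng(1)
        draws = draw_jurisdiction_means(2.8, 0.7, 1e6, 10000, rng)
        _, p = stats.kstest(draws, "norm", args=(2.8, 0.7))
        assert p > 0.01

    def test_truncated_positive(self):
        rng = np.random.default_rng(2)
        draws = draw_jurisdiction_means(0.5, 2.0, 2.0, 2000, rng)
        assert (draws > 0.1).all()


class TestCovariates:
    def test_zero_noise_exact_line(self):
        means = pd.Series([2.0, 3.0, 4.0], index=["a", "b", "c"])
        tab = simulate_covariates(means, slope=0.0125, noise_scale=0.0, intercept=1.0)
        np.testing.assert_allclose(
            1.0 + 0.0125 * tab["covid_deaths_per_100k"], tab["mean_delay_weeks"],
            rtol=1e-12,
        )
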