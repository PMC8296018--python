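"""Delay-estimation routes: exchangeability, degeneracies, pooling, outliers.

MCMC-based tests run at reduced draw counts; recovery-rate checks over many
seeds live in test_acceptance.py.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from excessnowcast.inference import (
    HierarchicalPosterior,
    fit_independent,
    fit_mixture,
    fit_nonparametric,
    fit_partial_pool,
    outlier_pvalues,
    outlier_scan,
)
from excessnowcast.mmwr import Snapshot, SnapshotSeries
from excessnowcast.simulate import SimulationConfig, simulate_dataset

FAST = dict(n_chains=2, n_warmup=300, n_draws=300)


def _clone_jurisdiction(series: SnapshotSeries, src: str, names: list[str]) -> SnapshotSeries:
    """A series in which every jurisdiction carries a copy of ``src``'s data."""
    snaps = []
    for s in series.snapshots:
        sub = s.counts(src)
        frames = [sub.assign(jurisdiction=n) for n in names]
        snaps.append(Snapshot(s.publication_date, pd.concat(frames), registry=names))
    return SnapshotSeries(snaps)


class TestIndependent:
    def test_identical_data_identical_estimates(self, small_world):
        series = _clone_jurisdiction(small_world.series, "Alabama", ["Alabama", "Alaska"])
        f1 = fit_independent(series, "Alabama", seed=5, **FAST)
        f2 = fit_independent(series, "Alaska", seed=5, **FAST)
        np.testing.assert_array_equal(f1.mean_draws, f2.mean_draws)
        np.testing.assert_array_equal(f1.sd_draws, f2.sd_draws)

    def test_delay_free_series_degenerate(self):
        cfg = SimulationConfig(
            n_jurisdictions=1, intercepts=(np.log(300.0),), masking=False, rng_seed=9
        )
        from excessnowcast.simulate import simulate_snapshots, simulate_true_deaths

        rng = np.random.default_rng(9)
        truth = simulate_true_deaths(cfg, rng)
        truth.delay_params["mean"] = 0.01
        truth.delay_params["sd"] = 0.005
        series = simulate_snapshots(truth, masking=False, rng=rng)
        fit = fit_independent(series, "Alabama", seed=1, **FAST)
        assert fit.degenerate
        # everything already reported: the estimated mean sits below the
        # first resolvable reporting bin
        assert float(np.median(fit.mean_draws)) < 10 / 7


class TestMixture:
    def test_zero_count_series_gives_uniform_component_probs(self):
        from conftest import make_snapshot

        rows = lambda c: [("Alabama", 2020, w, c) for w in (40, 41, 42)]
        series = SnapshotSeries([
            make_snapshot(dt.date(2020, 11, 4), rows(0)),
            make_snapshot(dt.date(2020, 11, 11), rows(0)),
            make_snapshot(dt.date(2021, 6, 2), rows(0)),
        ])
        fit = fit_mixture(series, "Alabama", seed=2, **FAST)
        # with equal component likelihoods the posterior component
        # probabilities reduce to the uniform prior weights; the Monte-Carlo
        # average over the simplex draws carries O(1/sqrt(n_draws)) noise
        np.testing.assert_allclose(fit.component_probs, [1 / 3] * 3, atol=0.05)

    def test_weights_on_simplex(self, small_world):
        fit = fit_mixture(small_world.series, "Alabama", seed=3, **FAST)
        w = fit.point().weights
        assert sum(w) == pytest.approx(1.0, abs=1e-12)
        flat = fit.weight_draws.reshape(-1, 3)
        np.testing.assert_allclose(flat.sum(axis=1), 1.0, atol=1e-12)

    def test_heavy_tail_selects_lognormal(self):
        cfg = SimulationConfig(
            n_jurisdictions=1, intercepts=(np.log(1500.0),), delay_sd=5.6,
            sigma_mu_true=1e-6, rng_seed=21, masking=False,
        )
        ds = simulate_dataset(cfg)
        fit = fit_mixture(ds.series, "Alabama", seed=4, **FAST)
        assert fit.component_probs[2] > 0.5  # lognormal dominates


class TestNonparametric:
    def test_cross_method_mean_agreement(self, small_world):
        """Hazard-based and parametric mean delays agree on well-behaved data
        (the two estimation routes overlay)."""
        hz = fit_nonparametric(small_world.series, "Arizona", seed=6, **FAST)
        ind = fit_independent(small_world.series, "Arizona", seed=6, **FAST)
        assert hz.point().mean_delay() == pytest.approx(
            float(np.median(ind.mean_draws)), abs=0.5
        )


class TestPartialPool:
    def test_identical_jurisdictions_shrink_sigma(self, small_world):
        names = ["Alabama", "Alaska", "Arizona", "Arkansas"]
        series = _clone_jurisdiction(small_world.series, "Alabama", names)
        post = fit_partial_pool(series, seed=7, **FAST)
        assert float(np.median(post.sigma_mu)) < 0.4

    def test_requires_three_jurisdictions(self, small_world):
        with pytest.raises(ValueError):
            fit_partial_pool(small_world.series,
                             excluded={"Alabama", "Alaska"}, seed=0, **FAST)

    def test_excluding_outlier_shrinks_sigma(self):
        cfg = SimulationConfig(n_jurisdictions=10, rng_seed=13,
                               outliers=(("Florida", 10.4),))
        ds = simulate_dataset(cfg)
        with_out = fit_partial_pool(ds.series, seed=8, **FAST)
        without = fit_partial_pool(ds.series, excluded={"Florida"}, seed=8, **FAST)
        assert float(np.median(without.sigma_mu)) < float(np.median(with_out.sigma_mu))


class TestOutliers:
    def test_center_gives_half(self):
        shape = (2, 50)
        post = HierarchicalPosterior(
            jurisdictions=["A", "B"],
            mu=np.full(shape, 2.8),
            sigma_mu=np.full(shape, 0.7),
            nu=np.full(shape, 5.0),
            theta=np.full((*shape, 2), 2.8),   # theta_j == mu in every draw
            sd=np.full((*shape, 2), 1.5),
            max_rhat=1.0,
        )
        pv = outlier_pvalues(post)
        np.testing.assert_allclose(pv.to_numpy(), 0.5, atol=1e-12)

    def test_scan_flags_planted_outlier_and_iterates(self):
        cfg = SimulationConfig(n_jurisdictions=10, rng_seed=17,
                               outliers=(("Delaware", 10.4),))
        ds = simulate_dataset(cfg)
        rep = outlier_scan(ds.series, seed=9, **FAST)
        assert "Delaware" in rep.flagged
        assert rep.pvalues["Delaware"] < 0.01
        assert len(rep.history) == len(rep.flagged) + 1  # final clean refit
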