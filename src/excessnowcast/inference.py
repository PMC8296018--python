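"""Reporting-delay estimation from snapshot series.

Four estimation routes, all sharing the Poisson snapshot likelihood of
:mod:`excessnowcast.likelihood`:

* :func:`fit_independent` — one (mean, sd) pair per jurisdiction, any of the
  three parametric families;
* :func:`fit_partial_pool` — hierarchical lognormal model in which the
  per-jurisdiction delay means scatter around a shared mean mu with
  Student's-t deviations (scale sigma_mu, dof nu), the heavy tail making the
  pool robust to outlying jurisdictions;
* :func:`fit_mixture` — gamma/Weibull/lognormal mixture with shared
  (mean, sd) and simplex weights pi, the whole-jurisdiction likelihood being
  the pi-weighted sum of the three family likelihoods;
* :func:`fit_nonparametric` — reverse-time discrete hazards g(1..D), D = 20
  weekly bins, g(0) = 1 imposed.

Outlier jurisdictions are detected from the partial-pool posterior: for each
draw, the Student's-t tail percentile of theta_j under that draw's
(nu, mu, sigma_mu); the per-jurisdiction median of min(F, 1-F) is the
reported P-value, and the scan iteratively excludes the most extreme
flagged jurisdiction and refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .distributions import (
    BIN0_BOUNDARY_WEEKS,
    MAX_DELAY_BINS,
    DiscreteHazardDelay,
    MixtureDelay,
    ParametricDelay,
    FAMILIES,
    family_cdf,
)
from .likelihood import CellData, poisson_loglik_cells, prepare_cells
from .mcmc import ScaleAdapter, adaptive_metropolis, split_rhat
from .mmwr import SnapshotSeries

__all__ = [
    "PriorConfig",
    "ParametricFit",
    "MixtureFit",
    "HazardFit",
    "HierarchicalPosterior",
    "OutlierReport",
    "fit_independent",
    "fit_partial_pool",
    "fit_mixture",
    "fit_nonparametric",
    "outlier_pvalues",
    "outlier_scan",
    "mean_delay",
    "fraction_within_10_days",
]


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors shared by all delay fits (weeks scale)."""

    mean_scale: float = 10.0      # half-normal sd for the delay mean
    sd_scale: float = 10.0        # half-normal sd for the delay sd
    sigma_mu_scale: float = 5.0   # half-normal sd for the pool scale
    nu_shape: float = 2.0         # gamma(shape, rate) prior on the dof
    nu_rate: float = 0.1


def _halfnormal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf


def _t_logpdf(x, nu, mu, sigma):
    z = (x - mu) / sigma
    return (
        special.gammaln((nu + 1) / 2)
        - special.gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1) / 2 * np.log1p(z * z / nu)
    )


def _quantiles(draws: np.ndarray, probs=(0.025, 0.25, 0.5, 0.75, 0.975)):
    return {f"q{p:g}": float(np.quantile(draws, p)) for p in probs}


def _warn_if_not_converged(max_rhat: float, what: str) -> None:
    if not np.isfinite(max_rhat) or max_rhat >= 1.05:
        warnings.warn(
            f"{what}: split-R-hat {max_rhat:.3f} exceeds 1.05; "
            "treat this posterior with caution (increase draws/warmup)",
            RuntimeWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# independent parametric fit


@dataclass
class ParametricFit:
    """Posterior over (mean, sd) for one jurisdiction and family."""

    jurisdiction: str
    family: str
    mean_draws: np.ndarray  # (chains, draws)
    sd_draws: np.ndarray
    max_rhat: float
    degenerate: bool = False

    def point(self) -> ParametricDelay:
        return ParametricDelay(
            self.family, float(np.median(self.mean_draws)), float(np.median(self.sd_draws))
        )

    def mean_interval(self, prob: float = 0.95) -> tuple[float, float]:
        a = (1 - prob) / 2
        return (
            float(np.quantile(self.mean_draws, a)),
            float(np.quantile(self.mean_draws, 1 - a)),
        )

    def delay_at(self, flat_index: int) -> ParametricDelay:
        m = self.mean_draws.reshape(-1)
        s = self.sd_draws.reshape(-1)
        i = flat_index % m.size
        return ParametricDelay(self.family, float(m[i]), float(s[i]))

    @property
    def n_flat_draws(self) -> int:
        return self.mean_draws.size

    def summary(self) -> pd.DataFrame:
        rows = [
            {"param": "mean", **_quantiles(self.mean_draws)},
            {"param": "sd", **_quantiles(self.sd_draws)},
        ]
        return pd.DataFrame(rows).assign(
            jurisdiction=self.jurisdiction, family=self.family
        )


def _cv_ok(mean: float, sd: float) -> bool:
    cv = sd / mean
    return 1e-3 < cv < 1e3


def fit_independent(
    series: SnapshotSeries,
    jurisdiction: str,
    family: str = "lognormal",
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    priors: PriorConfig = PriorConfig(),
    cells: CellData | None = None,
) -> ParametricFit:
    """Posterior over the delay (mean, sd) for a single jurisdiction."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if cells is None:
        cells = prepare_cells(series, jurisdiction)
    rng = np.random.default_rng(seed)

    def logpost(x: np.ndarray) -> float:
        u, v = x
        if not (-5 < u < 5 and -5 < v < 5):
            return -np.inf
        mean, sd = np.exp(u), np.exp(v)
        if not _cv_ok(mean, sd):
            return -np.inf
        F = family_cdf(family, mean, sd, cells.elapsed)
        return (
            poisson_loglik_cells(cells, F)
            + _halfnormal_lp(mean, priors.mean_scale)
            + _halfnormal_lp(sd, priors.sd_scale)
            + u + v  # log-scale Jacobians
        )

    res = adaptive_metropolis(
        logpost,
        np.log([2.5, 2.0]),
        rng=rng,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        blocks=[[0], [1]],
        jitter=0.3,
    )
    max_rhat = res.max_rhat()
    _warn_if_not_converged(max_rhat, f"independent {family} fit ({jurisdiction})")
    mean_draws = np.exp(res.chains[:, :, 0])
    sd_draws = np.exp(res.chains[:, :, 1])
    return ParametricFit(
        jurisdiction, family, mean_draws, sd_draws, max_rhat, cells.degenerate
    )


# ---------------------------------------------------------------------------
# mixture fit


@dataclass
class MixtureFit:
    jurisdiction: str
    weight_draws: np.ndarray  # (chains, draws, 3) order = FAMILIES
    mean_draws: np.ndarray
    sd_draws: np.ndarray
    component_probs: np.ndarray  # posterior-mean component probabilities
    max_rhat: float

    def point(self) -> MixtureDelay:
        w = np.median(self.weight_draws.reshape(-1, 3), axis=0)
        w = w / w.sum()
        return MixtureDelay(
            tuple(w), float(np.median(self.mean_draws)), float(np.median(self.sd_draws))
        )


def _stick_weights(a1: float, a2: float) -> tuple[np.ndarray, float]:
    """Two stick-breaking logits -> simplex weights + log-Jacobian (uniform
    simplex prior: density constant, only the transform Jacobian remains)."""
    s1, s2 = special.expit(a1), special.expit(a2)
    w1 = s1
    w2 = (1 - s1) * s2
    w3 = 1 - w1 - w2
    logjac = (
        np.log(s1) + np.log1p(-s1)            # d w1 / d a1
        + np.log1p(-s1) + np.log(s2) + np.log1p(-s2)  # d w2 / d a2
    )
    return np.array([w1, w2, w3]), float(logjac)


def fit_mixture(
    series: SnapshotSeries,
    jurisdiction: str,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    priors: PriorConfig = PriorConfig(),
    cells: CellData | None = None,
) -> MixtureFit:
    """Gamma/Weibull/lognormal mixture with shared (mean, sd).

    The jurisdiction-level likelihood is sum_i pi_i L_i(mean, sd); posterior
    component probabilities are the draw-wise normalised pi_i L_i averaged
    over the posterior.
    """
    if cells is None:
        cells = prepare_cells(series, jurisdiction)
    rng = np.random.default_rng(seed)

    def component_logliks(mean: float, sd: float) -> np.ndarray:
        return np.array([
            poisson_loglik_cells(cells, family_cdf(f, mean, sd, cells.elapsed))
            for f in FAMILIES
        ])

    def logpost(x: np.ndarray) -> float:
        u, v, a1, a2 = x
        if not (-5 < u < 5 and -5 < v < 5 and abs(a1) < 20 and abs(a2) < 20):
            return -np.inf
        mean, sd = np.exp(u), np.exp(v)
        if not _cv_ok(mean, sd):
            return -np.inf
        w, logjac = _stick_weights(a1, a2)
        lls = component_logliks(mean, sd)
        mix_ll = special.logsumexp(lls, b=w)
        return (
            mix_ll
            + _halfnormal_lp(mean, priors.mean_scale)
            + _halfnormal_lp(sd, priors.sd_scale)
            + u + v + logjac
        )

    res = adaptive_metropolis(
        logpost,
        np.array([np.log(2.5), np.log(2.0), 0.0, 0.0]),
        rng=rng,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        jitter=0.3,
    )
    max_rhat = res.max_rhat()
    _warn_if_not_converged(max_rhat, f"mixture fit ({jurisdiction})")

    flat = res.flat()
    weights = np.empty((flat.shape[0], 3))
    comp_post = np.zeros(3)
    # posterior component probabilities: average of pi_i L_i / sum_k pi_k L_k
    for i, x in enumerate(flat):
        w, _ = _stick_weights(x[2], x[3])
        weights[i] = w
        lls = component_logliks(float(np.exp(x[0])), float(np.exp(x[1])))
        logp = np.log(w) + lls
        comp_post += np.exp(logp - special.logsumexp(logp))
    comp_post /= flat.shape[0]

    shape = res.chains.shape[:2]
    return MixtureFit(
        jurisdiction,
        weights.reshape(*shape, 3),
        np.exp(res.chains[:, :, 0]),
        np.exp(res.chains[:, :, 1]),
        comp_post,
        max_rhat,
    )


# ---------------------------------------------------------------------------
# nonparametric hazard fit


@dataclass
class HazardFit:
    jurisdiction: str
    hazard_draws: np.ndarray  # (chains, draws, D+1) including g(0) = 1
    max_rhat: float

    def point(self) -> DiscreteHazardDelay:
        g = np.median(self.hazard_draws.reshape(-1, self.hazard_draws.shape[-1]), axis=0)
        g[0] = 1.0
        return DiscreteHazardDelay(tuple(g))

    def mean_delay_draws(self) -> np.ndarray:
        flat = self.hazard_draws.reshape(-1, self.hazard_draws.shape[-1])
        return np.array([DiscreteHazardDelay(tuple(g)).mean_delay() for g in flat])


def fit_nonparametric(
    series: SnapshotSeries,
    jurisdiction: str,
    *,
    D: int = MAX_DELAY_BINS,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    cells: CellData | None = None,
) -> HazardFit:
    """Reverse-time discrete-hazard fit: free hazards g(1..D), g(0) = 1.

    Uniform(0, 1) priors on each hazard; the implied CDF enters the same
    Poisson snapshot likelihood through the weekly binning of elapsed time
    (bin 0 = the first 10 days).
    """
    if cells is None:
        cells = prepare_cells(series, jurisdiction)
    rng = np.random.default_rng(seed)
    # cell -> hazard bin; eligible cells always have elapsed past bin 0
    d_cell = np.clip(
        np.floor(cells.elapsed - BIN0_BOUNDARY_WEEKS + 1e-12).astype(int), 0, D
    )

    def logpost(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 15):
            return -np.inf
        g = special.expit(x)
        one_minus = 1.0 - g
        F = np.empty(D + 1)
        F[-1] = 1.0
        F[:-1] = np.multiply.accumulate(one_minus[::-1])[::-1]
        ll = poisson_loglik_cells(cells, F[d_cell])
        logjac = float(np.sum(np.log(g) + np.log(one_minus)))
        return ll + logjac

    res = adaptive_metropolis(
        logpost,
        np.full(D, special.logit(0.25)),
        rng=rng,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        jitter=0.3,
    )
    max_rhat = res.max_rhat()
    _warn_if_not_converged(max_rhat, f"nonparametric fit ({jurisdiction})")
    g_draws = special.expit(res.chains)
    full = np.concatenate(
        [np.ones((*g_draws.shape[:2], 1)), g_draws], axis=2
    )
    return HazardFit(jurisdiction, full, max_rhat)


# ---------------------------------------------------------------------------
# hierarchical partial pool (lognormal family)


@dataclass
class HierarchicalPosterior:
    """Joint posterior of the partial-pool model.

    ``mu``/``sigma_mu``/``nu`` have shape (chains, draws); ``theta`` and
    ``sd`` have shape (chains, draws, J) aligned with ``jurisdictions``.
    """

    jurisdictions: list[str]
    mu: np.ndarray
    sigma_mu: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    sd: np.ndarray
    max_rhat: float

    def mu_interval(self, prob: float = 0.95) -> tuple[float, float]:
        a = (1 - prob) / 2
        return float(np.quantile(self.mu, a)), float(np.quantile(self.mu, 1 - a))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"param": "mu", **_quantiles(self.mu)},
            {"param": "sigma_mu", **_quantiles(self.sigma_mu)},
            {"param": "nu", **_quantiles(self.nu)},
        ]
        for k, j in enumerate(self.jurisdictions):
            rows.append({"param": f"theta[{j}]", **_quantiles(self.theta[:, :, k])})
        return pd.DataFrame(rows)


def fit_partial_pool(
    series: SnapshotSeries,
    jurisdictions: list[str] | None = None,
    *,
    family: str = "lognormal",
    excluded: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    priors: PriorConfig = PriorConfig(),
) -> HierarchicalPosterior:
    """Hierarchical fit of per-jurisdiction lognormal delay means theta_j with
    theta_j ~ Student-t(nu, mu, sigma_mu) constrained positive; per-jurisdiction
    sds are independent (half-normal priors).

    Structured Metropolis-within-Gibbs sweep: per-jurisdiction (theta_j, sd_j)
    block updates touch only that jurisdiction's likelihood; the hyperparameter
    updates touch only the Student-t layer.
    """
    if family != "lognormal":
        raise NotImplementedError("partial pool is implemented for the lognormal family")
    if jurisdictions is None:
        jurisdictions = series.jurisdictions
    jurisdictions = [j for j in jurisdictions if j not in set(excluded)]
    if len(jurisdictions) < 3:
        raise ValueError("need at least 3 non-excluded jurisdictions")
    J = len(jurisdictions)
    cells = [prepare_cells(series, j) for j in jurisdictions]
    log_el = [np.log(c.elapsed) for c in cells]
    rng = np.random.default_rng(seed)

    def ll_j(k: int, theta: float, s: float) -> float:
        sigma2 = np.log1p((s / theta) ** 2)
        mu_ln = np.log(theta) - sigma2 / 2
        F = special.ndtr((log_el[k] - mu_ln) / np.sqrt(sigma2))
        return poisson_loglik_cells(cells[k], F)

    def hyper_lp(mu: float, sig: float, nu: float, theta: np.ndarray) -> float:
        return (
            float(np.sum(_t_logpdf(theta, nu, mu, sig)))
            + _halfnormal_lp(mu, priors.mean_scale)
            + _halfnormal_lp(sig, priors.sigma_mu_scale)
            + (priors.nu_shape - 1) * np.log(nu) - priors.nu_rate * nu
        )

    n_iter = n_warmup + n_draws
    mu_out = np.empty((n_chains, n_draws))
    sig_out = np.empty((n_chains, n_draws))
    nu_out = np.empty((n_chains, n_draws))
    theta_out = np.empty((n_chains, n_draws, J))
    sd_out = np.empty((n_chains, n_draws, J))

    for c in range(n_chains):
        u = np.log(2.5) + 0.2 * rng.standard_normal(J)   # log theta_j
        v = np.log(2.0) + 0.2 * rng.standard_normal(J)   # log sd_j
        h = np.array([np.log(2.5), np.log(1.0), np.log(5.0)]) + 0.2 * rng.standard_normal(3)
        theta, s = np.exp(u), np.exp(v)
        mu_h, sig_h, nu_h = np.exp(h)
        ll_cache = np.array([ll_j(k, theta[k], s[k]) for k in range(J)])
        j_adapt = [ScaleAdapter(0.1, target=0.234) for _ in range(J)]
        h_adapt = [ScaleAdapter(0.1, target=0.44) for _ in range(3)]
        # per-jurisdiction proposal shapes, adapted to the warm-up history
        # (theta and sd are correlated under the censored likelihood)
        j_chol = [np.eye(2) for _ in range(J)]
        warm_hist = np.empty((n_warmup, J, 2))

        for it in range(n_iter):
            warm = it < n_warmup
            if warm:
                warm_hist[it, :, 0], warm_hist[it, :, 1] = u, v
                if it >= 150 and it % 50 == 0:
                    for k in range(J):
                        cov = np.cov(warm_hist[it - 100:it, k].T) + 1e-8 * np.eye(2)
                        j_chol[k] = np.linalg.cholesky(cov)
                        if it == 150:  # proposals now posterior-shaped
                            j_adapt[k] = ScaleAdapter(2.38 / np.sqrt(2), target=0.234)
            # per-jurisdiction block updates
            for k in range(J):
                du, dv = j_adapt[k].scale * (j_chol[k] @ rng.standard_normal(2))
                u_new, v_new = u[k] + du, v[k] + dv
                acc_prob = 0.0
                if abs(u_new) < 5 and abs(v_new) < 5:
                    th_new, s_new = np.exp(u_new), np.exp(v_new)
                    ll_new = ll_j(k, th_new, s_new)
                    delta = (
                        ll_new - ll_cache[k]
                        + float(_t_logpdf(th_new, nu_h, mu_h, sig_h))
                        - float(_t_logpdf(theta[k], nu_h, mu_h, sig_h))
                        + _halfnormal_lp(s_new, priors.sd_scale)
                        - _halfnormal_lp(s[k], priors.sd_scale)
                        + (u_new + v_new) - (u[k] + v[k])
                    )
                    acc_prob = float(np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
                    if rng.random() < acc_prob:
                        u[k], v[k] = u_new, v_new
                        theta[k], s[k] = th_new, s_new
                        ll_cache[k] = ll_new
                if warm:
                    j_adapt[k].update(acc_prob)
            # hyperparameter updates (componentwise on log scale); several
            # sub-sweeps per iteration -- they cost J Student-t evaluations
            # each, negligible next to the likelihood sweep, and the dof nu
            # is weakly identified so it needs the extra moves
            cur_hlp = hyper_lp(mu_h, sig_h, nu_h, theta) + h.sum()
            for _ in range(5):
                for m in range(3):
                    h_new = h.copy()
                    h_new[m] += h_adapt[m].scale * rng.standard_normal()
                    acc_prob = 0.0
                    if abs(h_new[m]) < 8:
                        mu_n, sig_n, nu_n = np.exp(h_new)
                        new_hlp = hyper_lp(mu_n, sig_n, nu_n, theta) + h_new.sum()
                        delta = new_hlp - cur_hlp
                        acc_prob = float(np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
                        if rng.random() < acc_prob:
                            h = h_new
                            mu_h, sig_h, nu_h = mu_n, sig_n, nu_n
                            cur_hlp = new_hlp
                    if warm:
                        h_adapt[m].update(acc_prob)
            if not warm:
                i = it - n_warmup
                mu_out[c, i], sig_out[c, i], nu_out[c, i] = mu_h, sig_h, nu_h
                theta_out[c, i] = theta
                sd_out[c, i] = s

    key = np.concatenate(
        [mu_out[:, :, None], sig_out[:, :, None], nu_out[:, :, None], theta_out], axis=2
    )
    max_rhat = float(np.nanmax(split_rhat(key)))
    _warn_if_not_converged(max_rhat, "partial-pool fit")
    return HierarchicalPosterior(
        list(jurisdictions), mu_out, sig_out, nu_out, theta_out, sd_out, max_rhat
    )


# ---------------------------------------------------------------------------
# outlier detection


@dataclass
class OutlierReport:
    """Iterative outlier scan over partial-pool posteriors.

    ``pvalues`` are from the initial (no-exclusion) fit; ``history`` records
    the P-values of each refit with the cumulative exclusion set.
    """

    threshold: float
    pvalues: pd.Series
    flagged: list[str]
    history: list[dict]

    @property
    def flagged_set(self) -> set[str]:
        return set(self.flagged)


def outlier_pvalues(posterior: HierarchicalPosterior) -> pd.Series:
    """Median (over draws) two-sided Student's-t tail percentile of each
    theta_j under the draw's (nu, mu, sigma_mu): P = min(F, 1 - F)."""
    z = (posterior.theta - posterior.mu[:, :, None]) / posterior.sigma_mu[:, :, None]
    F = stats.t.cdf(z, posterior.nu[:, :, None])
    P = np.minimum(F, 1.0 - F)
    med = np.median(P.reshape(-1, P.shape[-1]), axis=0)
    return pd.Series(med, index=posterior.jurisdictions, name="median_pvalue")


def outlier_scan(
    series: SnapshotSeries,
    jurisdictions: list[str] | None = None,
    *,
    threshold: float = 0.025,
    max_rounds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> OutlierReport:
    """Flag the most extreme jurisdiction (median P < threshold), refit
    excluding it, and repeat until no jurisdiction is flagged."""
    flagged: list[str] = []
    history: list[dict] = []
    pvalues0: pd.Series | None = None
    for round_ in range(max_rounds):
        post = fit_partial_pool(
            series, jurisdictions, excluded=frozenset(flagged),
            seed=seed + round_, **fit_kwargs,
        )
        pv = outlier_pvalues(post)
        if pvalues0 is None:
            pvalues0 = pv
        history.append({"excluded": tuple(flagged), "pvalues": pv})
        worst = pv.idxmin()
        if pv[worst] < threshold:
            flagged.append(str(worst))
        else:
            break
    return OutlierReport(threshold, pvalues0, flagged, history)


# ---------------------------------------------------------------------------
# delay summaries (thin wrappers over the common delay contract)


def mean_delay(delay) -> float:
    """Mean reporting delay in weeks for any delay object."""
    return float(delay.mean_delay())


def fraction_within_10_days(delay) -> float:
    """Fraction of deaths reported within the first 10 days (the bin-0
    boundary of the discrete hazard)."""
    return float(delay.fraction_within_10_days())
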