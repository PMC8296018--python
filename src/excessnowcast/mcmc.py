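"""Adaptive random-walk Metropolis machinery.

All Bayesian fits in this package run on a small, dependency-free MCMC
engine: blocked Gaussian random-walk Metropolis on an unconstrained
parameter vector (callers apply log/logit transforms and add the Jacobian
terms to their log-posterior).  Proposal scales are adapted during warm-up
by Robbins-Monro stochastic approximation towards the usual optimal
acceptance rates (0.44 for scalar blocks, 0.234 for multivariate blocks).
Split-R-hat and effective sample sizes come from ``arviz``.

The models here are low-dimensional (2-20 unconstrained parameters) with
concentrated, unimodal posteriors, for which adaptive random walk mixes
well; the hierarchical partial-pool fit uses its own structured sweep in
:mod:`excessnowcast.inference` built on the same :class:`ScaleAdapter`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import arviz as az
import numpy as np

__all__ = ["ScaleAdapter", "SampleResult", "adaptive_metropolis", "split_rhat"]

RHAT_TOLERANCE = 1.01  # convergence guideline recorded with every fit


class ScaleAdapter:
    """Robbins-Monro adaptation of a log proposal scale during warm-up."""

    def __init__(self, init_scale: float = 0.1, target: float = 0.44) -> None:
        self.log_scale = float(np.log(init_scale))
        self.target = target
        self._step = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accept_prob: float) -> None:
        self._step += 1
        gamma = self._step ** -0.6
        self.log_scale += gamma * (accept_prob - self.target)


@dataclass
class SampleResult:
    """Posterior draws on the unconstrained scale, shape (chains, draws, dim)."""

    chains: np.ndarray
    accept_rate: np.ndarray
    logpost: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    def flat(self) -> np.ndarray:
        """All chains pooled, shape (chains*draws, dim)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def rhat(self) -> np.ndarray:
        return split_rhat(self.chains)

    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat()))

    @property
    def converged(self) -> bool:
        return self.max_rhat() < RHAT_TOLERANCE


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per dimension for draws of shape (chains, draws, dim)."""
    out = np.empty(chains.shape[-1])
    for k in range(chains.shape[-1]):
        out[k] = float(az.rhat(az.convert_to_dataset(chains[:, :, k]))["x"])
    return out


def adaptive_metropolis(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    *,
    rng: np.random.Generator,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    blocks: Sequence[Sequence[int]] | None = None,
    init_scale: float = 0.2,
    jitter: float = 0.5,
) -> SampleResult:
    """Sample an unconstrained log-posterior by blocked adaptive Metropolis.

    Parameters
    ----------
    logpost
        Log-posterior density (up to a constant) of the unconstrained vector.
        May return ``-inf`` outside the support.
    x0
        Starting point; each chain starts at ``x0`` plus Gaussian jitter.
    blocks
        Groups of coordinate indices updated jointly.  Default: one block
        per coordinate (componentwise updates).
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    if blocks is None:
        blocks = [[k] for k in range(dim)]
    blocks = [np.asarray(b, dtype=int) for b in blocks]

    chains = np.empty((n_chains, n_draws, dim))
    accept = np.zeros((n_chains, len(blocks)))
    lp_out = np.empty((n_chains, n_draws))

    for c in range(n_chains):
        x = x0 + jitter * rng.standard_normal(dim)
        lp = logpost(x)
        guard = 0
        while not np.isfinite(lp):  # jittered start fell off the support
            x = x0 + jitter * rng.standard_normal(dim) * 0.5 ** (guard + 1)
            lp = logpost(x)
            guard += 1
            if guard > 50:
                raise RuntimeError("could not find a finite starting point")
        adapters = [
            ScaleAdapter(init_scale, target=0.44 if len(b) == 1 else 0.234)
            for b in blocks
        ]
        for it in range(n_warmup + n_draws):
            warm = it < n_warmup
            for k, (b, adapter) in enumerate(zip(blocks, adapters)):
                prop = x.copy()
                prop[b] += adapter.scale * rng.standard_normal(len(b))
                lp_prop = logpost(prop)
                acc_prob = (
                    float(np.exp(min(0.0, lp_prop - lp))) if np.isfinite(lp_prop) else 0.0
                )
                if rng.random() < acc_prob:
                    x, lp = prop, lp_prop
                    if not warm:
                        accept[c, k] += 1
                if warm:
                    adapter.update(acc_prob)
            if not warm:
                chains[c, it - n_warmup] = x
                lp_out[c, it - n_warmup] = lp

    return SampleResult(
        chains=chains, accept_rate=accept / n_draws, logpost=lp_out
    )
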