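"""Bayesian per-generation mutation-rate estimation.

Pooling trios, the observed mutation count is modeled as

    sum_i X_i  ~  Poisson( sum_i 2 L_i (1 - beta_i) * mu )

where X_i is the observed DNM count in trio i, L_i its callable-site count,
and beta_i its false-negative rate; the factor 2 counts the two transmitted
gametes per site.  With the Jeffreys prior p(mu) proportional to 1/sqrt(mu)
(the reparameterization-invariant reference prior for a Poisson rate), the
posterior is conjugate:

    mu | data  ~  Gamma(shape = sum X_i + 1/2,  rate = sum_i 2 L_i (1 - beta_i)).

Because validation can fail at some candidate sites, the count is only known
to lie in [x_min, x_max]; conservative rate bounds take the 5th posterior
percentile under x_min and the 95th under x_max, and the point estimate
averages posterior means across the count bounds and the GC-filter on/off
scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "TrioCallable",
    "RatePosterior",
    "posterior_params",
    "posterior_quantile",
    "rate_bounds",
    "point_estimate",
    "per_trio_estimate",
    "high_variant_fold_elevation",
    "plot_posteriors",
]


@dataclass(frozen=True)
class TrioCallable:
    """One trio's inputs to the pooled rate model."""

    trio_id: str
    L: float        # callable sites
    beta: float     # false-negative rate
    x: int          # observed DNM count

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must be in [0, 1)")
        if self.x < 0:
            raise ValueError("x must be non-negative")

    @property
    def site_generations(self) -> float:
        """Effective site-generations surveyed: 2 L (1 - beta)."""
        return 2.0 * self.L * (1.0 - self.beta)


@dataclass(frozen=True)
class RatePosterior:
    """Gamma posterior on the per-site per-generation mutation rate."""

    shape: float       # sum(X) + 1/2
    rate_param: float  # T = sum 2 L_i (1 - beta_i)

    def __post_init__(self):
        if self.shape <= 0 or self.rate_param <= 0:
            raise ValueError("shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate_param

    def quantile(self, q: float) -> float:
        if not (0.0 < q < 1.0):
            raise ValueError("quantile level must be in (0, 1)")
        return float(stats.gamma.ppf(q, a=self.shape, scale=1.0 / self.rate_param))

    def pdf(self, mu) -> np.ndarray:
        return stats.gamma.pdf(np.asarray(mu), a=self.shape, scale=1.0 / self.rate_param)

    def sample(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.gamma(self.shape, 1.0 / self.rate_param, size=n)


def posterior_params(trio_callables: Sequence[TrioCallable]) -> RatePosterior:
    """Pooled Gamma posterior from per-trio (L, beta, x)."""
    trios = list(trio_callables)
    if not trios:
        raise ValueError("need at least one trio")
    total_x = sum(t.x for t in trios)
    T = sum(t.site_generations for t in trios)
    if T <= 0:
        raise ValueError("total site-generations is zero")
    return RatePosterior(shape=total_x + 0.5, rate_param=T)


def posterior_quantile(posterior: RatePosterior, q: float) -> float:
    return posterior.quantile(q)


def _with_count(trios: Sequence[TrioCallable], total_x: int) -> RatePosterior:
    T = sum(t.site_generations for t in trios)
    if T <= 0:
        raise ValueError("total site-generations is zero")
    return RatePosterior(shape=total_x + 0.5, rate_param=T)


def rate_bounds(
    x_min: int,
    x_max: int,
    trio_callables: Sequence[TrioCallable],
    quantiles: Tuple[float, float] = (0.05, 0.95),
) -> Tuple[float, float]:
    """Conservative rate bounds across the mutation-count uncertainty.

    Lower bound: the ``quantiles[0]`` percentile of the posterior built with
    the minimum count; upper: the ``quantiles[1]`` percentile with the
    maximum count.
    """
    if x_min > x_max:
        raise ValueError("x_min must not exceed x_max")
    trios = list(trio_callables)
    lower = _with_count(trios, x_min).quantile(quantiles[0])
    upper = _with_count(trios, x_max).quantile(quantiles[1])
    return lower, upper


def point_estimate(scenario_posteriors: Iterable[RatePosterior]) -> float:
    """Arithmetic mean of scenario posterior means (canonically 2x2: GC
    filter on/off crossed with the min/max mutation count)."""
    means = [p.mean for p in scenario_posteriors]
    if not means:
        raise ValueError("need at least one scenario posterior")
    return float(np.mean(means))


def per_trio_estimate(trio_callable: TrioCallable) -> float:
    """Poisson maximum-likelihood rate for a single trio: x / (2 L (1 - beta))."""
    T = trio_callable.site_generations
    if T <= 0:
        raise ValueError("L (1 - beta) must be positive")
    return trio_callable.x / T


def high_variant_fold_elevation(removed_fraction: float, rate_factor: float = 2.0) -> float:
    """Sensitivity of the genome-wide mean rate to filtered high-variant
    regions.

    If a fraction ``f`` of the genome was removed by the variant-density
    filter, the mutation rate there would need to be ``k`` times the rest of
    the genome's to change the genome-wide mean by ``rate_factor`` c, where
    (1 - f) + f k = c, i.e. k = (c - 1 + f) / f.  With f = 0.04 and c = 2 the
    removed regions would need a 26-fold elevated rate to double the mean —
    so a small filtered fraction cannot plausibly bias the estimate much.
    """
    if not (0.0 < removed_fraction < 1.0):
        raise ValueError("removed_fraction must be in (0, 1)")
    if rate_factor <= 0:
        raise ValueError("rate_factor must be positive")
    return (rate_factor - 1.0 + removed_fraction) / removed_fraction


def plot_posteriors(
    posteriors: Sequence[RatePosterior],
    labels: Sequence[str],
    path,
    mu_max: float | None = None,
) -> None:
    """Save a posterior-density plot for a set of rate posteriors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if mu_max is None:
        mu_max = max(p.quantile(0.999) for p in posteriors)
    grid = np.linspace(0.0, mu_max, 512)[1:]
    fig, ax = plt.subplots(figsize=(6, 4))
    for post, label in zip(posteriors, labels):
        ax.plot(grid, post.pdf(grid), label=label)
    ax.set_xlabel("mutation rate per site per generation")
    ax.set_ylabel("posterior density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
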