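"""False-negative-rate estimation by planting synthetic de novo mutations.

The FNR beta of a trio is the probability that a true DNM at a callable site
scores at or below the candidate cutoff and is therefore missed.  It is
estimated by *planting*: a synthetic DNM trio is assembled from real
genotype-likelihood triples — the offspring's triple drawn from a donor site
where the offspring and at least one parent are heterozygous (so the triple
reflects a genuine heterozygous read pileup), paired with two parental
triples drawn independently from clean sites with no alternative-allele
reads.  Each planted trio is scored exactly as real data; the fraction
missed, stratified by the donor offspring's sequencing depth and weighted by
the callable-site depth distribution, gives the overall beta:

    beta = sum_d  w_d * FNR_d,   w_d = fraction of callable sites at depth d.

Het-donor sites cannot themselves be callable (a heterozygous parent carries
alternative reads, which the parental-alt filter excludes), so donors are
taken from sites passing every filter *except* the parental-alt-read filter;
clean parental donors come from fully callable sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .genotype_model import (
    DN_SCORE_THRESHOLD,
    HET,
    PriorConfig,
    dn_score_array,
    ml_genotype,
)
from .site_filters import FATHER, MOTHER, OFFSPRING, TrioDataset

__all__ = [
    "DonorPools",
    "PlantedDnms",
    "FnrEstimate",
    "build_donor_pools",
    "simulate_planted_dnms",
    "estimate_fnr",
    "offspring_depth_distribution",
    "estimate_trio_fnr",
]

logger = logging.getLogger(__name__)


@dataclass
class DonorPools:
    """Donor genotype-likelihood triples for DNM planting.

    het_gl / het_depth: offspring triples (and their read depths) from sites
    where the offspring and >= 1 parent are heterozygous by maximum
    likelihood.  hom_gl: parental triples from callable sites with no
    alternative reads (two entries per site: mother's and father's).
    """

    het_gl: np.ndarray     # (M, 3)
    het_depth: np.ndarray  # (M,)
    hom_gl: np.ndarray     # (K, 3)

    def __post_init__(self):
        if len(self.het_gl) == 0:
            raise ValueError("het_pool is empty: no heterozygous-transmission donor sites")
        if len(self.hom_gl) == 0:
            raise ValueError("hom_pool is empty: no clean homozygous donor sites")


@dataclass
class PlantedDnms:
    """Synthetic DNM trios assembled from donor pools."""

    child_gl: np.ndarray   # (n, 3)
    mother_gl: np.ndarray  # (n, 3)
    father_gl: np.ndarray  # (n, 3)
    depth: np.ndarray      # (n,) donor offspring depth
    het_index: np.ndarray  # (n,) indices into the het pool
    hom_index: np.ndarray  # (n, 2) indices into the hom pool

    @property
    def n(self) -> int:
        return len(self.depth)


@dataclass
class FnrEstimate:
    """Depth-stratified FNR and the overall depth-weighted beta."""

    per_depth_fnr: Dict[int, float]
    depth_weights: Dict[int, float]          # renormalized over covered depths
    overall_beta: float
    n_planted: int
    excluded_depths: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.overall_beta <= 1.0):
            raise ValueError("overall_beta must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        depths = sorted(self.per_depth_fnr)
        return pd.DataFrame(
            {
                "depth": depths,
                "weight": [self.depth_weights[d] for d in depths],
                "fnr": [self.per_depth_fnr[d] for d in depths],
            }
        )


def build_donor_pools(
    dataset: TrioDataset, filter_fails: Mapping[str, np.ndarray]
) -> DonorPools:
    """Assemble donor pools from a trio's filter evaluation.

    ``filter_fails`` is the per-filter fail-array dict from
    :func:`pedmut.site_filters.evaluate_filters`.  "Heterozygous" means the
    maximum-likelihood genotype from the individual's likelihood triple.
    """
    names = [n for n in filter_fails if n != "parental_alt"]
    pass_other = ~np.logical_or.reduce([np.asarray(filter_fails[n]) for n in names])
    callable_mask = pass_other & ~np.asarray(filter_fails["parental_alt"])

    ml = ml_genotype(dataset.gl)  # (N, 3)
    het_sel = (
        pass_other
        & (ml[:, OFFSPRING] == HET)
        & ((ml[:, MOTHER] == HET) | (ml[:, FATHER] == HET))
    )
    # clean donors: fully callable sites with no alt reads in any member
    clean_sel = callable_mask & (dataset.alt_count.sum(axis=1) == 0)
    hom_gl = np.concatenate(
        [dataset.gl[clean_sel, MOTHER], dataset.gl[clean_sel, FATHER]], axis=0
    )
    return DonorPools(
        het_gl=dataset.gl[het_sel, OFFSPRING],
        het_depth=dataset.depth[het_sel, OFFSPRING],
        hom_gl=hom_gl,
    )


def simulate_planted_dnms(pools: DonorPools, n: int, seed: int) -> PlantedDnms:
    """Draw ``n`` synthetic DNM trios: one het-pool offspring triple paired
    with two independently drawn clean parental triples.  Deterministic under
    a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    het_idx = rng.integers(0, len(pools.het_gl), size=n)
    hom_idx = rng.integers(0, len(pools.hom_gl), size=(n, 2))
    return PlantedDnms(
        child_gl=pools.het_gl[het_idx],
        mother_gl=pools.hom_gl[hom_idx[:, 0]],
        father_gl=pools.hom_gl[hom_idx[:, 1]],
        depth=pools.het_depth[het_idx],
        het_index=het_idx,
        hom_index=hom_idx,
    )


def estimate_fnr(
    planted: PlantedDnms,
    depth_distribution: Mapping[int, float],
    prior_config: PriorConfig | None = None,
    threshold: float = DN_SCORE_THRESHOLD,
) -> FnrEstimate:
    """Score planted DNMs and combine per-depth miss fractions into beta.

    ``depth_distribution`` maps offspring depth -> fraction of callable sites
    at that depth.  Depths with weight but no planted draws are excluded and
    the remaining weights renormalized (logged).
    """
    prior_config = prior_config or PriorConfig()
    scores = dn_score_array(
        planted.child_gl, planted.mother_gl, planted.father_gl, prior_config
    )
    missed = ~(scores > threshold)  # a score of exactly `threshold` is not a candidate

    per_depth: Dict[int, float] = {}
    for d in np.unique(planted.depth):
        sel = planted.depth == d
        per_depth[int(d)] = float(missed[sel].mean())

    weights = {int(d): float(w) for d, w in depth_distribution.items() if w > 0}
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("depth distribution has no mass")
    if abs(total_w - 1.0) > 1e-9:
        weights = {d: w / total_w for d, w in weights.items()}

    covered = {d: w for d, w in weights.items() if d in per_depth}
    excluded = {d: w for d, w in weights.items() if d not in per_depth}
    if not covered:
        raise ValueError("no planted draws at any depth with callable-site weight")
    if excluded:
        logger.info(
            "FNR: %d depths with %.3f total weight had no planted draws; "
            "renormalizing over covered depths",
            len(excluded),
            sum(excluded.values()),
        )
    z = sum(covered.values())
    covered = {d: w / z for d, w in covered.items()}
    beta = float(sum(w * per_depth[d] for d, w in covered.items()))
    return FnrEstimate(
        per_depth_fnr=per_depth,
        depth_weights=covered,
        overall_beta=beta,
        n_planted=planted.n,
        excluded_depths=excluded,
    )


def offspring_depth_distribution(
    dataset: TrioDataset, callable_mask: np.ndarray
) -> Dict[int, float]:
    """Fraction of callable sites at each offspring sequencing depth."""
    depths = dataset.depth[np.asarray(callable_mask, dtype=bool), OFFSPRING]
    if len(depths) == 0:
        raise ValueError("no callable sites")
    vals, counts = np.unique(depths, return_counts=True)
    return {int(v): float(c) / len(depths) for v, c in zip(vals, counts)}


def estimate_trio_fnr(
    dataset: TrioDataset,
    filter_fails: Mapping[str, np.ndarray],
    callable_mask: np.ndarray,
    prior_config: PriorConfig | None = None,
    n_planted: int = 10_000,
    seed: int = 0,
) -> FnrEstimate:
    """Convenience wrapper: pools -> planting -> depth-weighted beta."""
    pools = build_donor_pools(dataset, filter_fails)
    planted = simulate_planted_dnms(pools, n_planted, seed)
    weights = offspring_depth_distribution(dataset, callable_mask)
    return estimate_fnr(planted, weights, prior_config)
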