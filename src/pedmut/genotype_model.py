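"""Trio genotype model: priors, Mendelian transmission with mutation, and the
de novo posterior score.

A biallelic site in a parent-offspring trio has 27 joint diploid genotype
configurations (offspring x mother x father, each in {hom-ref, het, hom-alt}).
Exactly one configuration is compatible with a germline de novo mutation
(DNM): the offspring heterozygous while both parents are homozygous for the
reference allele.  The de novo score of a site is the posterior mass on that
configuration,

    P(Gc, Gm, Gf | D) propto P(Dm|Gm) P(Df|Gf) P(Dc|Gc)
                             x P(Gc | Gm, Gf)   # transmission with mutation
                             x P(Gm, Gf | theta)  # parental heterozygosity

normalized over all 27 configurations.  The likelihood factors come from the
genotyper (VCF ``PL``/``GL`` fields) and are independent per individual; the
transmission term lets each parent pass one allele drawn uniformly from its
two, with a ref<->alt flip at probability ``mu_prior``; the parental prior
treats parents as independent draws from the population at heterozygosity
``theta``.

The score is a *ranking* statistic, not a calibrated probability: the prior
parameters are deliberately liberal (``mu_prior`` far above any plausible
per-site mutation rate, ``theta`` above the population heterozygosity) so that
true mutations are not lost before independent validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "HOMREF",
    "HET",
    "HOMALT",
    "GENOTYPES",
    "DNM_CONFIG",
    "DN_SCORE_THRESHOLD",
    "PriorConfig",
    "GenotypeLikelihoods",
    "transmission_prob",
    "parental_pair_prior",
    "log_config_prior",
    "dn_score",
    "dn_score_array",
    "genotype_likelihood_from_reads",
    "genotype_likelihoods_from_read_arrays",
    "pl_to_loglik",
    "gl_field_to_loglik",
]

HOMREF, HET, HOMALT = 0, 1, 2
GENOTYPES = ("homref", "het", "homalt")
_GT_INDEX = {name: i for i, name in enumerate(GENOTYPES)}

#: the unique trio configuration compatible with a de novo mutation:
#: offspring het, both parents hom-ref
DNM_CONFIG = (HET, HOMREF, HOMREF)

#: candidate cutoff on the de novo score (sites are candidates iff score
#: is strictly greater than this)
DN_SCORE_THRESHOLD = 0.3

_LN10 = math.log(10.0)


def _coerce_gt(gt) -> int:
    if isinstance(gt, str):
        try:
            return _GT_INDEX[gt]
        except KeyError:
            raise ValueError(f"invalid genotype label {gt!r}; expected one of {GENOTYPES}")
    gt = int(gt)
    if gt not in (HOMREF, HET, HOMALT):
        raise ValueError(f"invalid genotype code {gt}; expected 0, 1 or 2")
    return gt


@dataclass(frozen=True)
class PriorConfig:
    """Prior parameters entering the de novo score.

    mu_prior
        Assumed per-site per-generation mutation probability used *only*
        inside the score (default 1e-6 — deliberately high, to rank liberally).
    theta
        Population heterozygosity prior for the parents (default 0.008 —
        deliberately above realistic wolf heterozygosity ~0.0015, to guard
        against missed parental heterozygotes).
    """

    mu_prior: float = 1.0e-6
    theta: float = 0.008

    def __post_init__(self):
        if not (0.0 < self.mu_prior < 1.0):
            raise ValueError(f"mu_prior must be in (0, 1), got {self.mu_prior}")
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Natural-log likelihoods of one individual's reads under the three
    biallelic genotypes, normalized so the maximum entry is 0."""

    log_lik_homref: float
    log_lik_het: float
    log_lik_homalt: float

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "GenotypeLikelihoods":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (3,):
            raise ValueError("expected exactly three log-likelihood entries")
        if not np.all(np.isfinite(arr)):
            raise ValueError("log-likelihoods must be finite")
        arr = arr - arr.max()
        return cls(*arr.tolist())

    @classmethod
    def from_pl(cls, pl: Sequence[float]) -> "GenotypeLikelihoods":
        """From a phred-scaled ``PL`` triple (smallest entry 0)."""
        return cls.from_array(pl_to_loglik(pl))

    @classmethod
    def from_gl(cls, gl: Sequence[float]) -> "GenotypeLikelihoods":
        """From a VCF ``GL`` triple (log10 likelihoods)."""
        return cls.from_array(gl_field_to_loglik(gl))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.log_lik_homref, self.log_lik_het, self.log_lik_homalt], dtype=float
        )

    @property
    def is_uninformative(self) -> bool:
        """True when all three genotypes are equally likely (e.g. no reads)."""
        a = self.as_array()
        return bool(np.allclose(a, a[0]))


def pl_to_loglik(pl: Sequence[float]) -> np.ndarray:
    """Convert phred-scaled likelihoods to natural-log likelihoods.

    PL -> log-lik via ``-PL * ln(10) / 10``, then renormalized to max 0.
    """
    arr = -np.asarray(pl, dtype=float) * _LN10 / 10.0
    return arr - arr.max()


def gl_field_to_loglik(gl: Sequence[float]) -> np.ndarray:
    """Convert a VCF ``GL`` field (log10 likelihoods) to natural log, max 0."""
    arr = np.asarray(gl, dtype=float) * _LN10
    return arr - arr.max()


def transmission_prob(child_gt, mother_gt, father_gt, mu_prior: float) -> float:
    """P(child genotype | parental genotypes) under Mendelian transmission
    with mutation.

    Each parent transmits one allele chosen uniformly at random from its two;
    the transmitted allele then flips ref<->alt with probability ``mu_prior``.
    For fixed parents the three child genotypes sum to 1.
    """
    if not (0.0 <= mu_prior < 1.0):
        raise ValueError(f"mu_prior must be in [0, 1), got {mu_prior}")
    c = _coerce_gt(child_gt)
    m = _coerce_gt(mother_gt)
    f = _coerce_gt(father_gt)
    # probability each parent transmits the alt allele, after the flip
    p_alt = (mu_prior, 0.5, 1.0 - mu_prior)
    pm, pf = p_alt[m], p_alt[f]
    if c == HOMREF:
        return (1.0 - pm) * (1.0 - pf)
    if c == HET:
        return pm * (1.0 - pf) + (1.0 - pm) * pf
    return pm * pf


def parental_pair_prior(mother_gt, father_gt, theta: float) -> float:
    """Prior on the parental genotype pair at population heterozygosity theta.

    Parents are independent; each has P(het) = theta, P(hom-alt) = theta^2/4
    and the remaining mass on hom-ref.  Sums to 1 over the 9 pairs.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    m = _coerce_gt(mother_gt)
    f = _coerce_gt(father_gt)
    probs = (1.0 - theta - theta * theta / 4.0, theta, theta * theta / 4.0)
    if probs[0] <= 0.0:
        raise ValueError(f"theta={theta} leaves no mass on the hom-ref genotype")
    return probs[m] * probs[f]


@lru_cache(maxsize=32)
def _log_config_prior_cached(mu_prior: float, theta: float) -> np.ndarray:
    lp = np.empty((3, 3, 3), dtype=float)
    for gm in (HOMREF, HET, HOMALT):
        for gf in (HOMREF, HET, HOMALT):
            pair = parental_pair_prior(gm, gf, theta)
            for gc in (HOMREF, HET, HOMALT):
                p = pair * transmission_prob(gc, gm, gf, mu_prior)
                lp[gc, gm, gf] = math.log(p) if p > 0.0 else -math.inf
    return lp


def log_config_prior(prior: PriorConfig) -> np.ndarray:
    """Log joint prior over the 27 configurations, indexed [child, mother,
    father]; the exponentials sum to 1."""
    out = _log_config_prior_cached(prior.mu_prior, prior.theta)
    out = out.copy()
    out.setflags(write=False)
    return out


def _as_gl_matrix(gls, n_expected=None) -> np.ndarray:
    if isinstance(gls, GenotypeLikelihoods):
        arr = gls.as_array()[None, :]
    else:
        arr = np.asarray(gls, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("genotype likelihoods must have three entries per site")
    if not np.all(np.isfinite(arr)):
        raise ValueError("log-likelihoods must be finite")
    return arr


def dn_score_array(child_gl, mother_gl, father_gl, prior: PriorConfig | None = None) -> np.ndarray:
    """Vectorized de novo score for N sites.

    Parameters are (N, 3) arrays of natural-log likelihoods (any constant
    offset per individual is immaterial).  Returns the posterior mass on the
    DNM configuration at every site, computed in log space with a
    log-sum-exp normalization over all 27 configurations.
    """
    prior = prior or PriorConfig()
    c = _as_gl_matrix(child_gl)
    m = _as_gl_matrix(mother_gl)
    f = _as_gl_matrix(father_gl)
    if not (c.shape == m.shape == f.shape):
        raise ValueError("child, mother and father likelihood arrays must align")
    lp = log_config_prior(prior)
    # joint log posterior kernel over configurations: (N, 3, 3, 3)
    joint = (
        c[:, :, None, None]
        + m[:, None, :, None]
        + f[:, None, None, :]
        + lp[None, :, :, :]
    )
    total = logsumexp(joint.reshape(joint.shape[0], -1), axis=1)
    gc, gm, gf = DNM_CONFIG
    return np.exp(joint[:, gc, gm, gf] - total)


def dn_score(child_gl, mother_gl, father_gl, prior: PriorConfig | None = None) -> float:
    """De novo score DN_p of a single site: posterior probability that the
    offspring is heterozygous and both parents hom-ref, given the three
    genotype-likelihood triples.  In [0, 1]."""
    return float(dn_score_array(child_gl, mother_gl, father_gl, prior)[0])


def genotype_likelihoods_from_read_arrays(
    ref_count, alt_count, error_rate: float
) -> np.ndarray:
    """Vectorized biallelic read-pileup likelihoods.

    Each read is alt with probability ``error_rate`` under hom-ref, 1/2 under
    het, and ``1 - error_rate`` under hom-alt; reads are independent.  Returns
    (N, 3) natural-log likelihoods normalized to max 0 per site.  Sites with
    zero reads get a flat (uninformative) triple.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError(f"error_rate must be in (0, 1), got {error_rate}")
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])
    ll = alt[..., None] * np.log(p_alt) + ref[..., None] * np.log1p(-p_alt)
    return ll - ll.max(axis=-1, keepdims=True)


def genotype_likelihood_from_reads(
    ref_count: int, alt_count: int, error_rate: float
) -> GenotypeLikelihoods:
    """Likelihood triple for one individual from its ref/alt read counts."""
    ll = genotype_likelihoods_from_read_arrays(
        np.array([ref_count]), np.array([alt_count]), error_rate
    )[0]
    return GenotypeLikelihoods.from_array(ll)


def ml_genotype(gl: np.ndarray) -> np.ndarray:
    """Maximum-likelihood genotype index per site ((..., 3) -> (...,)).

    Ties resolve to the lowest genotype index (hom-ref first), which is the
    conservative choice for de novo screening.
    """
    return np.argmax(np.asarray(gl), axis=-1)
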