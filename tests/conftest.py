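"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pedmut.site_filters import TrioDataset, apply_filters
from pedmut.synthetic_data import SimulationParams, simulate_trio_study


# ---------------------------------------------------------------------------
# independent brute-force oracle for the de novo score (explicit enumeration
# of the 27 trio genotype configurations with plain-float products; kept free
# of any pedmut internals)


def oracle_transmission(child, mother, father, mu):
    """Transmission probability by exhaustive enumeration of the 2x2 gamete
    choices and flip outcomes."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    total = 0.0
    for am in alleles[mother]:
        for af in alleles[father]:
            for flip_m in (False, True):
                for flip_f in (False, True):
                    p = 0.25
                    p *= mu if flip_m else (1.0 - mu)
                    p *= mu if flip_f else (1.0 - mu)
                    tm = 1 - am if flip_m else am
                    tf = 1 - af if flip_f else af
                    if tm + tf == child:
                        total += p
    return total


def oracle_pair_prior(mother, father, theta):
    probs = (1.0 - theta - theta * theta / 4.0, theta, theta * theta / 4.0)
    return probs[mother] * probs[father]


def oracle_dn_score(child_gl, mother_gl, father_gl, mu, theta):
    """Posterior mass on (child het, parents hom-ref) by direct summation
    over all 27 configurations."""
    num = 0.0
    tot = 0.0
    for gc in range(3):
        for gm in range(3):
            for gf in range(3):
                w = (
                    math.exp(child_gl[gc])
                    * math.exp(mother_gl[gm])
                    * math.exp(father_gl[gf])
                    * oracle_pair_prior(gm, gf, theta)
                    * oracle_transmission(gc, gm, gf, mu)
                )
                tot += w
                if (gc, gm, gf) == (1, 0, 0):
                    num += w
    return num / tot


# ---------------------------------------------------------------------------
# dataset builders


def make_dataset(
    n: int,
    depth: int = 30,
    error: float = 0.01,
    chrom: str = "1",
    spacing: int = 1,
) -> TrioDataset:
    """A clean all-hom-ref trio dataset: every site has `depth` reads, zero
    alt reads, well-behaved annotations."""
    from pedmut.genotype_model import genotype_likelihoods_from_read_arrays

    depths = np.full((n, 3), depth, dtype=np.int64)
    alts = np.zeros((n, 3), dtype=np.int64)
    gl = np.stack(
        [
            genotype_likelihoods_from_read_arrays(depths[:, j] - alts[:, j], alts[:, j], error)
            for j in range(3)
        ],
        axis=1,
    )
    return TrioDataset(
        chrom=np.full(n, chrom, dtype=object),
        pos=np.arange(1, n * spacing + 1, spacing, dtype=np.int64),
        ref=np.full(n, "A", dtype="U1"),
        alt=np.full(n, "G", dtype="U1"),
        depth=depths,
        alt_count=alts,
        gl=gl,
        qd=np.full(n, 15.0),
        mq_rank_sum=np.zeros(n),
        gap_read_count=np.zeros(n, dtype=np.int64),
        deletion_read_fraction=np.zeros(n, dtype=float),
    )


def set_reads(dataset: TrioDataset, i: int, individual: int, depth: int, alt: int, error: float = 0.01):
    """Overwrite one individual's pileup at site i and refresh its GL."""
    from pedmut.genotype_model import genotype_likelihoods_from_read_arrays

    dataset.depth[i, individual] = depth
    dataset.alt_count[i, individual] = alt
    dataset.gl[i, individual] = genotype_likelihoods_from_read_arrays(
        np.array([depth - alt]), np.array([alt]), error
    )[0]


def random_gl_triples(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid normalized log-likelihood triples, shape (n, 3)."""
    gl = rng.uniform(-30.0, 0.0, size=(n, 3))
    return gl - gl.max(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# shared simulations (session scope: several modules reuse them)


@pytest.fixture(scope="session")
def sim20k():
    return simulate_trio_study(SimulationParams(n_sites=20_000, seed=11))


@pytest.fixture(scope="session")
def filtered20k(sim20k):
    mask, summary, fails = apply_filters(
        sim20k.dataset, sim20k.repeat_mask, sim20k.reference
    )
    return mask, summary, fails
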