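"""Synthetic all-sites trio datasets with known truth.

The generator emulates the statistical structure the analysis assumes: at
every site the parents carry Hardy-Weinberg genotypes at a true population
heterozygosity, the offspring receives one allele from each parent, and —
at otherwise hom-ref x hom-ref sites — a de novo mutation flips one
transmitted allele with probability 2*mu_true (one chance per gamete).
Sequencing is modeled as Poisson read depth per individual with per-read
base errors, giving binomial allele counts and the same likelihood triples
the genotyper would emit.  A reference sequence with GC-rich tracts and a
repeat annotation exercise the region filters, and labeled artifact channels
reproduce the false-positive sources real pipelines face: missed parental
heterozygotes, gap-carrying reads, mismapped reads, and deletion-heavy
sites.

The true rate (default 1e-4 per site) is deliberately elevated relative to
genome-scale rates (~1e-9) so that desk-scale simulations of 1e5 sites carry
a workable number of mutations; the rate machinery is scale-free in
2 L (1 - beta) mu, so nothing else changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .genotype_model import HET, HOMALT, HOMREF, genotype_likelihoods_from_read_arrays
from .site_filters import FATHER, MOTHER, OFFSPRING, RepeatMask, TrioDataset

__all__ = [
    "SimulationParams",
    "TrioSimulation",
    "ConfusionCounts",
    "simulate_trio_dataset",
    "inject_artifacts",
    "simulate_trio_study",
    "evaluate_against_truth",
    "validation_from_truth",
]

_BASES = np.array(["A", "C", "G", "T"])
_GC = {"G", "C"}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic trio.

    Defaults are the conditions the recovery analyses run under: 1e5 sites,
    true rate 1e-4 per site per generation, 25x mean coverage, 1% per-read
    base error, true heterozygosity 0.0015 (realistic for wolves; the
    *scoring* prior deliberately uses a larger value).  Artifact-channel
    rates are small but produce testable counts at the default size.
    """

    n_sites: int = 100_000
    theta_true: float = 0.0015
    mu_true: float = 1.0e-4
    mean_coverage: float = 25.0
    base_error_rate: float = 0.01
    repeat_fraction: float = 0.30
    gc_tract_fraction: float = 0.05
    gap_artifact_rate: float = 0.005
    mismap_artifact_rate: float = 0.002
    missed_het_rate: float = 0.002
    deletion_artifact_rate: float = 0.002
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in (
            "theta_true",
            "mu_true",
            "base_error_rate",
            "repeat_fraction",
            "gc_tract_fraction",
            "gap_artifact_rate",
            "mismap_artifact_rate",
            "missed_het_rate",
            "deletion_artifact_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.base_error_rate < 1.0):
            raise ValueError("base_error_rate must be in (0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TrioSimulation:
    """A generated trio dataset with its reference, repeat annotation and
    per-site truth table."""

    dataset: TrioDataset
    reference: Dict[str, str]
    repeats: List[Tuple[str, int, int]]  # 0-based half-open BED intervals
    truth: pd.DataFrame
    params: SimulationParams

    @property
    def repeat_mask(self) -> RepeatMask:
        intervals: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in self.repeats:
            intervals.setdefault(chrom, []).append((s, e))
        return RepeatMask(intervals)


def _draw_reference(rng: np.random.Generator, params: SimulationParams) -> Tuple[str, np.ndarray]:
    """Reference sequence with GC-rich tracts; returns (sequence, gc_prob)."""
    n = params.n_sites
    gc_prob = np.full(n, 0.41)  # genome-wide background GC content
    tract_len = 200
    n_tracts = int(round(n * params.gc_tract_fraction / tract_len))
    for start in rng.integers(0, max(1, n - tract_len), size=n_tracts):
        gc_prob[start : start + tract_len] = 0.75
    is_gc = rng.random(n) < gc_prob
    pick_half = rng.integers(0, 2, size=n)  # G vs C, A vs T
    bases = np.where(is_gc, np.where(pick_half == 0, "G", "C"), np.where(pick_half == 0, "A", "T"))
    return "".join(bases), gc_prob


def _draw_repeats(rng: np.random.Generator, params: SimulationParams) -> List[Tuple[str, int, int]]:
    n = params.n_sites
    tract_len = 500
    n_tracts = int(round(n * params.repeat_fraction / tract_len))
    out = []
    for start in sorted(rng.integers(0, max(1, n - tract_len), size=n_tracts)):
        out.append((params.chrom, int(start), int(min(start + tract_len, n))))
    return out


def _alt_bases(rng: np.random.Generator, ref_bases: np.ndarray) -> np.ndarray:
    """A non-reference alternative base per site."""
    offsets = rng.integers(1, 4, size=len(ref_bases))
    ref_idx = np.searchsorted(_BASES, ref_bases)
    return _BASES[(ref_idx + offsets) % 4]


def _read_counts(
    rng: np.random.Generator, genotypes: np.ndarray, mean_coverage: float, error: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson depths and binomial alt-allele counts for one individual."""
    depth = rng.poisson(mean_coverage, size=len(genotypes))
    p_alt = np.array([error, 0.5, 1.0 - error])[genotypes]
    alt = rng.binomial(depth, p_alt)
    return depth, alt


def simulate_trio_dataset(params: SimulationParams) -> TrioSimulation:
    """Generate a clean (artifact-free) all-sites trio dataset.

    Deterministic and byte-identical under a fixed seed.  Artifact channels
    are added separately by :func:`inject_artifacts`.
    """
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_sites
    theta = params.theta_true

    ref_seq, _ = _draw_reference(rng, params)
    repeats = _draw_repeats(rng, params)
    ref_bases = np.frombuffer(ref_seq.encode(), dtype="S1").astype("U1")
    alt_bases = _alt_bases(rng, ref_bases)

    # parental genotypes under the HWE-style prior at theta_true
    gt_probs = np.array([1.0 - theta - theta * theta / 4.0, theta, theta * theta / 4.0])
    mother_gt = rng.choice(3, size=n, p=gt_probs)
    father_gt = rng.choice(3, size=n, p=gt_probs)

    # Mendelian transmission: each parent passes its alt allele with
    # probability 0 / 0.5 / 1 by genotype
    p_alt_transmit = np.array([0.0, 0.5, 1.0])
    m_allele = (rng.random(n) < p_alt_transmit[mother_gt]).astype(np.int8)
    f_allele = (rng.random(n) < p_alt_transmit[father_gt]).astype(np.int8)

    # de novo mutations: at otherwise hom-ref x hom-ref sites, one of the two
    # transmitted gametes mutates ref->alt with probability mu_true each
    both_homref = (mother_gt == HOMREF) & (father_gt == HOMREF)
    dnm = both_homref & (rng.random(n) < 2.0 * params.mu_true)
    mutate_maternal = rng.random(n) < 0.5
    m_allele = np.where(dnm & mutate_maternal, 1, m_allele)
    f_allele = np.where(dnm & ~mutate_maternal, 1, f_allele)
    child_gt = (m_allele + f_allele).astype(np.int64)

    depth = np.empty((n, 3), dtype=np.int64)
    alt_count = np.empty((n, 3), dtype=np.int64)
    for j, gts in ((OFFSPRING, child_gt), (MOTHER, mother_gt), (FATHER, father_gt)):
        depth[:, j], alt_count[:, j] = _read_counts(
            rng, gts, params.mean_coverage, params.base_error_rate
        )

    gl = np.stack(
        [
            genotype_likelihoods_from_read_arrays(
                depth[:, j] - alt_count[:, j], alt_count[:, j], params.base_error_rate
            )
            for j in range(3)
        ],
        axis=1,
    )

    # quality annotations: typical-range values for clean sites
    qd = np.clip(rng.normal(15.0, 4.0, size=n), 0.1, None)
    mq_rank_sum = rng.normal(0.0, 0.8, size=n)

    dataset = TrioDataset(
        chrom=np.full(n, params.chrom, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64),
        ref=ref_bases,
        alt=alt_bases,
        depth=depth,
        alt_count=alt_count,
        gl=gl,
        qd=qd,
        mq_rank_sum=mq_rank_sum,
        gap_read_count=np.zeros(n, dtype=np.int64),
        deletion_read_fraction=np.zeros(n, dtype=float),
    )
    truth = pd.DataFrame(
        {
            "chrom": dataset.chrom,
            "pos": dataset.pos,
            "child_gt": child_gt,
            "mother_gt": mother_gt,
            "father_gt": father_gt,
            "is_dnm": dnm,
            "artifact": np.full(n, "", dtype=object),
        }
    )
    return TrioSimulation(
        dataset=dataset,
        reference={params.chrom: ref_seq},
        repeats=repeats,
        truth=truth,
        params=params,
    )


def inject_artifacts(sim: TrioSimulation, params: SimulationParams | None = None) -> TrioSimulation:
    """Add labeled artifact channels to a clean simulation.

    Channels (each applied to an independent random site subset at its rate):
    missed parental heterozygotes (a parent is truly het and transmitted the
    alternative allele, but its alternative reads dropped out — the classic
    false-positive source), gap-read sites, mismapped-read sites (spurious
    low-fraction offspring alt reads with depressed MQRankSum), and
    deletion-heavy sites.  Truth rows are relabeled; DNM indicators never
    change.
    """
    params = params or sim.params
    rng = np.random.default_rng([params.seed, 1])
    n = sim.dataset.n_sites
    ds = sim.dataset.copy()
    truth = sim.truth.copy()
    error = params.base_error_rate

    def _pick(rate: float, available: np.ndarray) -> np.ndarray:
        k = rng.binomial(n, rate)
        pool = np.flatnonzero(available)
        if k == 0 or len(pool) == 0:
            return np.array([], dtype=np.int64)
        return rng.choice(pool, size=min(k, len(pool)), replace=False)

    untouched = truth["artifact"].to_numpy() == ""

    # (a) missed parental heterozygote: mother becomes het in truth, child
    # inherits her alt allele, but the mother's pileup shows no alt reads
    idx = _pick(params.missed_het_rate, untouched & ~truth["is_dnm"].to_numpy())
    if len(idx):
        truth.loc[idx, "mother_gt"] = HET
        truth.loc[idx, "child_gt"] = np.maximum(truth.loc[idx, "child_gt"], HET)
        for j, gts in ((OFFSPRING, np.full(len(idx), HET)), (MOTHER, np.full(len(idx), HOMREF))):
            d = rng.poisson(params.mean_coverage, size=len(idx))
            a = rng.binomial(d, np.array([error, 0.5, 1.0 - error])[gts])
            ds.depth[idx, j] = d
            ds.alt_count[idx, j] = a
            ds.gl[idx, j] = genotype_likelihoods_from_read_arrays(d - a, a, error)
        truth.loc[idx, "artifact"] = "missed_het"
        untouched[idx] = False

    # (b) gap-carrying reads
    idx = _pick(params.gap_artifact_rate, untouched)
    if len(idx):
        ds.gap_read_count[idx] = 3 + rng.poisson(2.0, size=len(idx))
        truth.loc[idx, "artifact"] = "gap"
        untouched[idx] = False

    # (c) mismapped reads: spurious offspring alt reads at low fraction,
    # MQRankSum pushed below -2
    idx = _pick(params.mismap_artifact_rate, untouched)
    if len(idx):
        extra = 1 + rng.binomial(ds.depth[idx, OFFSPRING], 0.08)
        ds.alt_count[idx, OFFSPRING] += extra
        ds.depth[idx, OFFSPRING] += extra
        ds.gl[idx, OFFSPRING] = genotype_likelihoods_from_read_arrays(
            ds.depth[idx, OFFSPRING] - ds.alt_count[idx, OFFSPRING],
            ds.alt_count[idx, OFFSPRING],
            error,
        )
        ds.mq_rank_sum[idx] = -2.1 - np.abs(rng.normal(0.0, 1.0, size=len(idx)))
        truth.loc[idx, "artifact"] = "mismap"
        untouched[idx] = False

    # (d) deletion-heavy sites
    idx = _pick(params.deletion_artifact_rate, untouched)
    if len(idx):
        ds.deletion_read_fraction[idx] = 0.051 + np.abs(rng.normal(0.0, 0.05, size=len(idx)))
        truth.loc[idx, "artifact"] = "deletion"

    return TrioSimulation(
        dataset=ds, reference=sim.reference, repeats=sim.repeats, truth=truth, params=sim.params
    )


def simulate_trio_study(params: SimulationParams) -> TrioSimulation:
    """Clean simulation plus artifact channels — the full study conditions."""
    return inject_artifacts(simulate_trio_dataset(params), params)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    @property
    def empirical_fnr(self) -> float:
        total = self.tp + self.fn
        return self.fn / total if total else float("nan")


def evaluate_against_truth(
    candidates: pd.DataFrame,
    truth_table: pd.DataFrame,
    callable_positions: np.ndarray | pd.DataFrame,
) -> ConfusionCounts:
    """Confusion counts of the candidate list against the truth table.

    TP: candidates that are true DNMs.  FN: true DNMs at callable sites
    absent from the candidate list.  The empirical FNR FN / (TP + FN) is the
    direct counterpart of the planting-based beta.
    """
    truth_keys = set(zip(truth_table["chrom"].astype(str), truth_table["pos"].astype(int)))
    cand_keys = set(zip(candidates["chrom"].astype(str), candidates["pos"].astype(int)))
    unknown = cand_keys - truth_keys
    if unknown:
        raise KeyError(f"{len(unknown)} candidate sites are missing from the truth table")
    dnm = truth_table[truth_table["is_dnm"]]
    dnm_keys = set(zip(dnm["chrom"].astype(str), dnm["pos"].astype(int)))
    if isinstance(callable_positions, pd.DataFrame):
        callable_keys = set(
            zip(callable_positions["chrom"].astype(str), callable_positions["pos"].astype(int))
        )
    else:
        chrom = truth_table["chrom"].astype(str).to_numpy()
        pos = truth_table["pos"].astype(int).to_numpy()
        mask = np.asarray(callable_positions, dtype=bool)
        callable_keys = set(zip(chrom[mask], pos[mask]))
    tp = len(cand_keys & dnm_keys)
    fp = len(cand_keys - dnm_keys)
    fn = len((dnm_keys & callable_keys) - cand_keys)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def validation_from_truth(candidates: pd.DataFrame, truth_table: pd.DataFrame) -> pd.DataFrame:
    """Synthetic stand-in for independent (Sanger) validation: a candidate is
    confirmed iff the truth table marks it a real DNM, otherwise a false
    positive."""
    dnm = truth_table[truth_table["is_dnm"]]
    dnm_keys = set(zip(dnm["chrom"].astype(str), dnm["pos"].astype(int)))
    status = [
        "confirmed" if (str(c), int(p)) in dnm_keys else "false_positive"
        for c, p in zip(candidates["chrom"], candidates["pos"])
    ]
    return pd.DataFrame(
        {"chrom": candidates["chrom"], "pos": candidates["pos"], "status": status}
    )
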