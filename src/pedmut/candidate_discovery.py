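"""Candidate de novo mutations: discovery, quality triage, and mutation-count
bounds from validation outcomes.

A callable site becomes a candidate when the offspring shows at least one
alternative read (the parents show none, by the callable definition) and the
de novo score exceeds 0.3 — a deliberately liberal cutoff, balancing false
negatives against the number of sites needing manual alignment review and
independent (Sanger) validation.  The pipeline emits a machine-readable
candidate report annotated with quality-metric percentiles against the
trio's own background; the user returns a validation-status table
(confirmed / false_positive / failed / untested), from which the minimum and
maximum plausible mutation counts are derived: sites whose validation assay
*failed* might or might not be real mutations, so they bound the count from
above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_model import DN_SCORE_THRESHOLD, PriorConfig, dn_score_array
from .site_filters import FATHER, MOTHER, OFFSPRING, TrioDataset

__all__ = [
    "VALID_STATUSES",
    "QD_FLAG_THRESHOLD",
    "MQRS_FLAG_THRESHOLD",
    "MutationCountBounds",
    "QualityBackground",
    "find_candidates",
    "quality_background",
    "mutation_count_bounds",
    "write_candidate_report",
    "read_validation_statuses",
]

VALID_STATUSES = frozenset({"confirmed", "false_positive", "failed", "untested"})

# triage heuristics: candidates below these tend to be false positives
QD_FLAG_THRESHOLD = 4.0
MQRS_FLAG_THRESHOLD = -2.0

CANDIDATE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "dn_score",
    "offspring_alt_reads",
    "qd",
    "mq_rank_sum",
]


@dataclass(frozen=True)
class MutationCountBounds:
    """Bounds on the observed DNM count: x_min counts only confirmed
    mutations, x_max additionally treats every failed validation as real."""

    x_min: int
    x_max: int

    def __post_init__(self):
        if self.x_min < 0 or self.x_max < self.x_min:
            raise ValueError("require 0 <= x_min <= x_max")


def find_candidates(
    dataset: TrioDataset,
    callable_mask: np.ndarray,
    prior_config: PriorConfig | None = None,
    threshold: float = DN_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Rank candidate DNMs among callable sites.

    Candidates require >= 1 offspring alt read, zero parental alt reads and a
    de novo score strictly above ``threshold``.  Sorted by descending score,
    ties broken by (chrom, pos) for determinism.
    """
    prior_config = prior_config or PriorConfig()
    callable_mask = np.asarray(callable_mask, dtype=bool)
    pre = (
        callable_mask
        & (dataset.alt_count[:, OFFSPRING] >= 1)
        & (dataset.alt_count[:, MOTHER] == 0)
        & (dataset.alt_count[:, FATHER] == 0)
    )
    idx = np.flatnonzero(pre)
    if len(idx) == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    scores = dn_score_array(
        dataset.gl[idx, OFFSPRING],
        dataset.gl[idx, MOTHER],
        dataset.gl[idx, FATHER],
        prior_config,
    )
    keep = scores > threshold  # strict: a score of exactly `threshold` is excluded
    idx, scores = idx[keep], scores[keep]
    df = pd.DataFrame(
        {
            "chrom": dataset.chrom[idx],
            "pos": dataset.pos[idx],
            "ref": dataset.ref[idx],
            "alt": dataset.alt[idx],
            "dn_score": scores,
            "offspring_alt_reads": dataset.alt_count[idx, OFFSPRING],
            "qd": dataset.qd[idx],
            "mq_rank_sum": dataset.mq_rank_sum[idx],
        }
    )
    df = df.sort_values(
        ["dn_score", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


class QualityBackground:
    """Empirical distributions of QD and MQRankSum among callable sites with
    at least one offspring alternative read — the comparison set for judging
    whether a candidate's quality metrics are typical."""

    def __init__(self, qd: np.ndarray, mq_rank_sum: np.ndarray):
        qd = np.sort(np.asarray(qd, dtype=float))
        mq = np.sort(np.asarray(mq_rank_sum, dtype=float))
        if len(qd) == 0:
            raise ValueError("empty quality background (no conditioned sites)")
        self._qd = qd[~np.isnan(qd)]
        self._mq = mq[~np.isnan(mq)]
        if len(self._qd) == 0 or len(self._mq) == 0:
            raise ValueError("quality background has no finite values")

    def percentile(self, metric: str, values) -> np.ndarray:
        """Percentile (0-100) of each value in the background ECDF."""
        ref = {"qd": self._qd, "mq_rank_sum": self._mq}[metric]
        ranks = np.searchsorted(ref, np.asarray(values, dtype=float), side="right")
        return 100.0 * ranks / len(ref)

    def annotate(self, candidates: pd.DataFrame) -> pd.DataFrame:
        """Add percentile columns and false-positive triage flags."""
        out = candidates.copy()
        out["qd_percentile"] = self.percentile("qd", out["qd"].to_numpy())
        out["mq_percentile"] = self.percentile("mq_rank_sum", out["mq_rank_sum"].to_numpy())
        flags = []
        for qd, mq in zip(out["qd"], out["mq_rank_sum"]):
            f = []
            if qd < QD_FLAG_THRESHOLD:
                f.append("low_qd")
            if mq < MQRS_FLAG_THRESHOLD:
                f.append("low_mq")
            flags.append(";".join(f))
        out["flags"] = flags
        return out


def quality_background(
    dataset: TrioDataset, callable_mask: np.ndarray
) -> QualityBackground:
    """Build the trio's quality background from callable sites with >= 1
    offspring alternative read."""
    mask = np.asarray(callable_mask, dtype=bool) & (dataset.alt_count[:, OFFSPRING] >= 1)
    if not mask.any():
        raise ValueError("no callable sites with an offspring alternative read")
    return QualityBackground(dataset.qd[mask], dataset.mq_rank_sum[mask])


def mutation_count_bounds(statuses: Iterable[str] | Mapping | pd.DataFrame) -> MutationCountBounds:
    """Bound the observed mutation count from validation outcomes.

    x_min counts confirmed DNMs; x_max adds validation failures (which may be
    real mutations).  False positives contribute to neither; untested
    candidates were never advanced to validation and are excluded.
    """
    if isinstance(statuses, pd.DataFrame):
        values = statuses["status"].tolist()
    elif isinstance(statuses, Mapping):
        values = list(statuses.values())
    else:
        values = list(statuses)
    bad = sorted(set(values) - VALID_STATUSES)
    if bad:
        raise ValueError(f"unknown validation status labels: {bad}")
    confirmed = sum(1 for s in values if s == "confirmed")
    failed = sum(1 for s in values if s == "failed")
    return MutationCountBounds(x_min=confirmed, x_max=confirmed + failed)


def write_candidate_report(candidates: pd.DataFrame, path) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_validation_statuses(path) -> pd.DataFrame:
    """Read a validation-status TSV with columns (chrom, pos, status)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"validation table is missing columns: {sorted(missing)}")
    bad = sorted(set(df["status"]) - VALID_STATUSES)
    if bad:
        raise ValueError(f"unknown validation status labels: {bad}")
    return df
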