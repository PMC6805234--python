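"""Descriptive statistics on confirmed de novo mutations.

Confirmed DNMs are compared against transmitted (inherited) variants passing
the same filters: the strand-collapsed substitution spectrum, a Monte-Carlo
multinomial test for excess mutations on a focal chromosome, and an exact
binomial test for subtelomeric enrichment (subtelomere = 5 Mb from each end
of an assembled chromosome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUBTELOMERE_WINDOW",
    "SUBSTITUTION_CLASSES",
    "GenomeLayout",
    "ChromosomeTestResult",
    "SpectrumResult",
    "is_subtelomeric",
    "subtelomere_fraction",
    "chromosome_excess_test",
    "subtelomeric_excess_test",
    "spectrum_table",
]

SUBTELOMERE_WINDOW = 5_000_000

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# strand-collapsed classes; purine-reference substitutions fold onto their
# complements (A>G with T>C, etc.)
SUBSTITUTION_CLASSES = (
    "A:T>G:C",  # transition
    "C:G>T:A",  # transition
    "A:T>C:G",
    "A:T>T:A",
    "C:G>A:T",
    "C:G>G:C",
)
TRANSITION_CLASSES = frozenset({"A:T>G:C", "C:G>T:A"})


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths and the subtelomere window size (bases from each
    chromosome end)."""

    chromosome_lengths: Mapping[str, int]
    subtelomere_window: int = SUBTELOMERE_WINDOW

    def __post_init__(self):
        if self.subtelomere_window <= 0:
            raise ValueError("subtelomere_window must be positive")

    def length(self, chrom: str) -> int:
        try:
            return int(self.chromosome_lengths[chrom])
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def is_fully_subtelomeric(self, chrom: str) -> bool:
        """Short chromosomes (length <= 2 windows) are entirely subtelomeric."""
        return self.length(chrom) <= 2 * self.subtelomere_window


def is_subtelomeric(chrom: str, pos: int, layout: GenomeLayout) -> bool:
    """True iff the 1-based position lies within the subtelomere window of
    either chromosome end: pos <= w or pos > length - w."""
    length = layout.length(chrom)
    if not (1 <= pos <= length):
        raise ValueError(f"position {pos} outside chromosome {chrom} (length {length})")
    w = layout.subtelomere_window
    return pos <= w or pos > length - w


def subtelomere_fraction(layout: GenomeLayout) -> float:
    """Fraction of the genome that is subtelomeric (a simple background
    proportion when transmitted-variant positions are unavailable)."""
    total = sum(int(v) for v in layout.chromosome_lengths.values())
    sub = sum(
        min(2 * layout.subtelomere_window, int(v))
        for v in layout.chromosome_lengths.values()
    )
    return sub / total


@dataclass(frozen=True)
class ChromosomeTestResult:
    """Monte-Carlo multinomial tail test for a focal chromosome."""

    pvalue: float
    pvalue_bonferroni: float
    observed: int
    expected: float
    focal_chrom: str
    n_mc: int


def chromosome_excess_test(
    dnm_counts_by_chrom: Mapping[str, int],
    background_proportions: Mapping[str, float],
    focal_chrom: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> ChromosomeTestResult:
    """Probability, under multinomial sampling at the background chromosome
    proportions, that the focal chromosome's DNM count reaches the observed
    one.

    The focal chromosome is caller-specified (it was identified in the
    observed data) and the per-chromosome tail probability is reported
    without multiplicity correction; a Bonferroni-adjusted value (times the
    number of chromosomes) is attached alongside.
    """
    chroms = list(background_proportions)
    if focal_chrom not in chroms:
        raise ValueError(f"focal chromosome {focal_chrom!r} not in background")
    probs = np.array([background_proportions[c] for c in chroms], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("background proportions must be non-negative and sum to 1")
    counts = {c: int(dnm_counts_by_chrom.get(c, 0)) for c in chroms}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("zero total DNMs")
    observed = counts[focal_chrom]
    rng = np.random.default_rng(seed)
    focal_idx = chroms.index(focal_chrom)
    draws = rng.multinomial(n_total, probs, size=n_mc)[:, focal_idx]
    p = float(np.mean(draws >= observed))
    return ChromosomeTestResult(
        pvalue=p,
        pvalue_bonferroni=min(1.0, p * len(chroms)),
        observed=observed,
        expected=float(n_total * probs[focal_idx]),
        focal_chrom=focal_chrom,
        n_mc=n_mc,
    )


def subtelomeric_excess_test(
    n_subtelomeric: int, n_total: int, background_proportion: float
) -> float:
    """One-sided exact binomial upper-tail probability of observing at least
    ``n_subtelomeric`` subtelomeric DNMs out of ``n_total`` at the background
    proportion."""
    if not (0.0 <= background_proportion <= 1.0):
        raise ValueError("background_proportion must be in [0, 1]")
    if not (0 <= n_subtelomeric <= n_total):
        raise ValueError("require 0 <= n_subtelomeric <= n_total")
    if n_total == 0:
        return 1.0
    return float(
        stats.binomtest(
            n_subtelomeric, n_total, background_proportion, alternative="greater"
        ).pvalue
    )


def _collapse(ref: str, alt: str) -> str | None:
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP or ref == alt:
        return None
    if ref in ("G", "T"):  # fold purine/T references onto the A/C strand
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}:{_COMP[ref]}>{alt}:{_COMP[alt]}"


@dataclass
class SpectrumResult:
    """Substitution-class counts/proportions with transition/transversion
    totals for the DNM and background lists."""

    table: pd.DataFrame
    dnm_ts: int
    dnm_tv: int
    background_ts: int
    background_tv: int
    n_excluded: int


def _records(records) -> Iterable[Tuple[str, str]]:
    if isinstance(records, pd.DataFrame):
        return zip(records["ref"], records["alt"])
    return records


def spectrum_table(dnm_list, background_variant_list) -> SpectrumResult:
    """Strand-collapsed substitution spectrum of DNMs versus transmitted
    (background) variants.  Non-ACGT or degenerate records are excluded."""
    counts = {name: {c: 0 for c in SUBSTITUTION_CLASSES} for name in ("dnm", "background")}
    excluded = 0
    for name, records in (("dnm", dnm_list), ("background", background_variant_list)):
        for ref, alt in _records(records):
            cls = _collapse(str(ref), str(alt))
            if cls is None:
                excluded += 1
                continue
            counts[name][cls] += 1
    rows = []
    totals = {name: sum(counts[name].values()) for name in counts}
    for cls in SUBSTITUTION_CLASSES:
        rows.append(
            {
                "class": cls,
                "is_transition": cls in TRANSITION_CLASSES,
                "dnm_count": counts["dnm"][cls],
                "dnm_prop": counts["dnm"][cls] / totals["dnm"] if totals["dnm"] else 0.0,
                "background_count": counts["background"][cls],
                "background_prop": (
                    counts["background"][cls] / totals["background"]
                    if totals["background"]
                    else 0.0
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    ts = {n: sum(v for c, v in counts[n].items() if c in TRANSITION_CLASSES) for n in counts}
    return SpectrumResult(
        table=table,
        dnm_ts=ts["dnm"],
        dnm_tv=totals["dnm"] - ts["dnm"],
        background_ts=ts["background"],
        background_tv=totals["background"] - ts["background"],
        n_excluded=excluded,
    )
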