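"""Per-trio site filtering: the callable genome and its size L.

The mutation-rate denominator is the number of sites at which a de novo
mutation *could* have been observed in a trio.  Seven per-site filters define
it, applied in a fixed order for stage-count reporting (each is a pure
per-site predicate, so the final callable set is order-independent):

repeat        site falls in a repeat-masked interval (BED)
missing       zero sequencing depth in any trio member, or more than 5% of
              spanning reads carry deletions
depth         coverage < 10x or > 100x in any trio member
parental_alt  one or more alternative-allele reads in either parent
density       four or more other variant sites within 200 bases on either
              side (variant site = any trio member with >= 1 alt read)
gap           three or more reads at the site contain alignment gaps
gc            > 60% GC in the 100 bases surrounding the site (toggleable;
              rates are reported with and without it)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .genotype_model import GenotypeLikelihoods

__all__ = [
    "INDIVIDUALS",
    "FILTER_ORDER",
    "TrioSite",
    "TrioDataset",
    "FilterConfig",
    "CallableSummary",
    "RepeatMask",
    "gc_fraction",
    "evaluate_filters",
    "site_filter_flags",
    "apply_filters",
    "count_callable",
    "estimate_filter_fraction_by_sampling",
]

#: column order of the per-individual axes in TrioDataset arrays
INDIVIDUALS = ("offspring", "mother", "father")
OFFSPRING, MOTHER, FATHER = 0, 1, 2

FILTER_ORDER = ("repeat", "missing", "depth", "parental_alt", "density", "gap", "gc")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the callable-site filter chain."""

    depth_min: int = 10
    depth_max: int = 100
    deletion_fraction_max: float = 0.05
    density_window: int = 200          # bases on either side
    density_max_variants: int = 3      # fail at >= density_max_variants + 1
    gap_reads_max: int = 2             # fail at >= gap_reads_max + 1
    gc_window: int = 100               # bases surrounding the site
    gc_max: float = 0.60
    gc_filter_enabled: bool = True
    # heterozygosity prior for the per-individual genotype call behind the
    # density filter's "variant site" definition
    density_call_theta: float = 0.008

    def __post_init__(self):
        if self.depth_min <= 0 or self.depth_max <= 0:
            raise ValueError("depth thresholds must be positive")
        if self.depth_min >= self.depth_max:
            raise ValueError("depth_min must be below depth_max")
        for name in ("deletion_fraction_max", "gc_max"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("density_window", "density_max_variants", "gap_reads_max", "gc_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrioSite:
    """One genomic site in a trio (scalar view; bulk analysis uses
    :class:`TrioDataset`)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depths: Tuple[int, int, int]          # offspring, mother, father
    alt_counts: Tuple[int, int, int]
    gls: Tuple[GenotypeLikelihoods, GenotypeLikelihoods, GenotypeLikelihoods]
    qd: float = float("nan")
    mq_rank_sum: float = float("nan")
    gap_read_count: int = 0
    deletion_read_fraction: float = 0.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def ref_counts(self) -> Tuple[int, int, int]:
        return tuple(d - a for d, a in zip(self.depths, self.alt_counts))


@dataclass
class TrioDataset:
    """Columnar all-sites table for one trio.

    Per-individual arrays have shape (n_sites, 3) in the order offspring,
    mother, father.  ``gl`` holds natural-log likelihood triples with shape
    (n_sites, 3, 3): site x individual x genotype.
    """

    chrom: np.ndarray          # (N,) str
    pos: np.ndarray            # (N,) int, 1-based
    ref: np.ndarray            # (N,) str single bases
    alt: np.ndarray            # (N,) str single bases
    depth: np.ndarray          # (N, 3) int
    alt_count: np.ndarray      # (N, 3) int
    gl: np.ndarray             # (N, 3, 3) float
    qd: np.ndarray             # (N,) float
    mq_rank_sum: np.ndarray    # (N,) float
    gap_read_count: np.ndarray           # (N,) int
    deletion_read_fraction: np.ndarray   # (N,) float

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def ref_count(self) -> np.ndarray:
        return self.depth - self.alt_count

    def site(self, i: int) -> TrioSite:
        return TrioSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=str(self.alt[i]),
            depths=tuple(int(d) for d in self.depth[i]),
            alt_counts=tuple(int(a) for a in self.alt_count[i]),
            gls=tuple(GenotypeLikelihoods.from_array(self.gl[i, j]) for j in range(3)),
            qd=float(self.qd[i]),
            mq_rank_sum=float(self.mq_rank_sum[i]),
            gap_read_count=int(self.gap_read_count[i]),
            deletion_read_fraction=float(self.deletion_read_fraction[i]),
        )

    def subset(self, mask_or_index) -> "TrioDataset":
        idx = np.asarray(mask_or_index)
        return TrioDataset(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            depth=self.depth[idx],
            alt_count=self.alt_count[idx],
            gl=self.gl[idx],
            qd=self.qd[idx],
            mq_rank_sum=self.mq_rank_sum[idx],
            gap_read_count=self.gap_read_count[idx],
            deletion_read_fraction=self.deletion_read_fraction[idx],
        )

    def copy(self) -> "TrioDataset":
        return TrioDataset(**{k: np.copy(v) for k, v in self.__dict__.items()})

    def is_sorted(self) -> bool:
        """Sorted by (chrom, pos): positions strictly increase within each
        contiguous chromosome block and chromosomes do not interleave."""
        if self.n_sites < 2:
            return True
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            return False
        seen: List[str] = []
        for c in self.chrom:
            c = str(c)
            if not seen or seen[-1] != c:
                if c in seen:
                    return False
                seen.append(c)
        return True


@dataclass
class CallableSummary:
    """Sites surviving each sequential filter stage, and the final callable
    count L used as the rate denominator."""

    n_input: int
    stage_counts: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def callable_count(self) -> int:
        return self.stage_counts[-1][1] if self.stage_counts else self.n_input

    def to_frame(self):
        import pandas as pd

        rows = [("input", self.n_input)] + list(self.stage_counts)
        return pd.DataFrame(rows, columns=["stage", "sites"])

    def validate_monotone(self) -> None:
        counts = [self.n_input] + [c for _, c in self.stage_counts]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError("stage counts must be non-increasing")


class RepeatMask:
    """Repeat-annotation intervals (e.g. RepeatMasker output as BED),
    queryable by 1-based position."""

    def __init__(self, intervals: Mapping[str, Iterable[Tuple[int, int]]]):
        # store merged, sorted, 0-based half-open intervals per chromosome
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            merged: List[List[int]] = []
            for s, e in sorted((int(s), int(e)) for s, e in ivs):
                if e <= s:
                    raise ValueError(f"empty interval ({s}, {e}) on {chrom}")
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @classmethod
    def from_bed(cls, path) -> "RepeatMask":
        intervals: Dict[str, List[Tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls(intervals)

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorized membership for 1-based positions."""
        pos0 = np.asarray(pos, dtype=np.int64) - 1
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos0[inside] < self._ends[chrom][idx[inside]]
        return inside

    def intervals(self, chrom: str) -> List[Tuple[int, int]]:
        return list(zip(self._starts.get(chrom, ()), self._ends.get(chrom, ())))

    @property
    def chroms(self) -> List[str]:
        return list(self._starts)


def gc_fraction(reference_window: str) -> float:
    """GC fraction of a reference window: (#G + #C) / (#A + #C + #G + #T).

    Ambiguous bases are excluded from numerator and denominator; an
    all-ambiguous window is undefined (NaN) and the caller fails the GC
    filter conservatively.
    """
    window = reference_window.upper()
    gc = sum(1 for b in window if b in "GC")
    acgt = sum(1 for b in window if b in "ACGT")
    if acgt == 0:
        return math.nan
    return gc / acgt


def _gc_fail_for_chrom(
    seq: str, pos: np.ndarray, config: FilterConfig
) -> np.ndarray:
    """Vectorized GC filter over 1-based positions on one chromosome.

    The window is the site +- gc_window/2, excluding the site base itself and
    clipped at chromosome ends.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    cs_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cs_n = np.concatenate([[0], np.cumsum(is_acgt)])
    half = config.gc_window // 2
    if np.any(pos < 1) or np.any(pos > len(arr)):
        raise ValueError("site position outside the reference sequence")
    lo = np.maximum(pos - half, 1) - 1          # 0-based inclusive start
    hi = np.minimum(pos + half, len(arr))       # 0-based exclusive end
    gc = cs_gc[hi] - cs_gc[lo]
    n = cs_n[hi] - cs_n[lo]
    site0 = pos - 1
    gc = gc - is_gc[site0]
    n = n - is_acgt[site0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, gc / np.maximum(n, 1), np.nan)
    return (n == 0) | (frac > config.gc_max)


def _variant_calls(dataset: TrioDataset, config: FilterConfig) -> np.ndarray:
    """Per-site variant flag: any trio member's MAP genotype (GL plus the
    log heterozygosity prior) is non-hom-ref."""
    from .genotype_model import HOMREF

    theta = config.density_call_theta
    log_prior = np.log(
        np.array([1.0 - theta - theta * theta / 4.0, theta, theta * theta / 4.0])
    )
    map_gt = np.argmax(dataset.gl + log_prior[None, None, :], axis=-1)
    return np.any(map_gt != HOMREF, axis=1)


def _chrom_blocks(chroms: np.ndarray):
    """Yield (chrom, slice) for contiguous chromosome blocks."""
    n = len(chroms)
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            yield str(chroms[start]), slice(start, i)
            start = i


def evaluate_filters(
    dataset: TrioDataset,
    repeat_mask: RepeatMask | None,
    reference: Mapping[str, str] | None,
    config: FilterConfig | None = None,
) -> Dict[str, np.ndarray]:
    """Evaluate every filter independently on every site.

    Returns a dict mapping filter name -> boolean array of sites *failing*
    that filter.  ``reference`` maps chromosome name to sequence and is
    required when the GC filter is enabled.
    """
    config = config or FilterConfig()
    n = dataset.n_sites
    fails: Dict[str, np.ndarray] = {}

    if repeat_mask is None:
        fails["repeat"] = np.zeros(n, dtype=bool)
    else:
        rep = np.zeros(n, dtype=bool)
        for chrom, sl in _chrom_blocks(dataset.chrom):
            rep[sl] = repeat_mask.contains(chrom, dataset.pos[sl])
        fails["repeat"] = rep

    fails["missing"] = np.any(dataset.depth == 0, axis=1) | (
        dataset.deletion_read_fraction > config.deletion_fraction_max
    )
    fails["depth"] = np.any(
        (dataset.depth < config.depth_min) | (dataset.depth > config.depth_max), axis=1
    )
    fails["parental_alt"] = np.any(dataset.alt_count[:, (MOTHER, FATHER)] >= 1, axis=1)

    # density: other variant sites within +- density_window.  A "variant
    # site" is one where any trio member's MAP genotype under the
    # single-individual heterozygosity prior is non-hom-ref.  A genotype
    # *call* is required here: raw >=1-alt-read evidence (and, at low
    # coverage, even bare maximum-likelihood calls) is dominated by
    # sequencing error and would mark most of the genome variant.
    variant = _variant_calls(dataset, config)
    dens = np.zeros(n, dtype=bool)
    for chrom, sl in _chrom_blocks(dataset.chrom):
        pos = dataset.pos[sl]
        vpos = pos[variant[sl]]
        lo = np.searchsorted(vpos, pos - config.density_window, side="left")
        hi = np.searchsorted(vpos, pos + config.density_window, side="right")
        neighbors = hi - lo - variant[sl].astype(int)
        dens[sl] = neighbors > config.density_max_variants
    fails["density"] = dens

    fails["gap"] = dataset.gap_read_count > config.gap_reads_max

    if config.gc_filter_enabled:
        if reference is None:
            raise ValueError("GC filter enabled but no reference sequence supplied")
        gc = np.zeros(n, dtype=bool)
        for chrom, sl in _chrom_blocks(dataset.chrom):
            if chrom not in reference:
                raise KeyError(f"chromosome {chrom!r} missing from the reference")
            gc[sl] = _gc_fail_for_chrom(str(reference[chrom]), dataset.pos[sl], config)
        fails["gc"] = gc
    else:
        fails["gc"] = np.zeros(n, dtype=bool)

    return fails


def site_filter_flags(
    site: TrioSite,
    repeat_mask: RepeatMask | None = None,
    reference_context: str | None = None,
    config: FilterConfig | None = None,
    n_density_neighbors: int = 0,
) -> set:
    """Filters a single site FAILS; the empty set means callable.

    ``reference_context`` is the gc_window-wide sequence surrounding the site
    (site base excluded), required when the GC filter is enabled.
    ``n_density_neighbors`` is the number of other variant sites within the
    density window, which a single-site view cannot know by itself.
    """
    config = config or FilterConfig()
    flags = set()
    if repeat_mask is not None and bool(repeat_mask.contains(site.chrom, [site.pos])[0]):
        flags.add("repeat")
    if any(d == 0 for d in site.depths) or (
        site.deletion_read_fraction > config.deletion_fraction_max
    ):
        flags.add("missing")
    if any(d < config.depth_min or d > config.depth_max for d in site.depths):
        flags.add("depth")
    if site.alt_counts[MOTHER] >= 1 or site.alt_counts[FATHER] >= 1:
        flags.add("parental_alt")
    if n_density_neighbors > config.density_max_variants:
        flags.add("density")
    if site.gap_read_count > config.gap_reads_max:
        flags.add("gap")
    if config.gc_filter_enabled:
        if reference_context is None:
            raise ValueError("GC filter enabled but no reference context supplied")
        frac = gc_fraction(reference_context)
        if math.isnan(frac) or frac > config.gc_max:
            flags.add("gc")
    return flags


def apply_filters(
    dataset: TrioDataset,
    repeat_mask: RepeatMask | None,
    reference: Mapping[str, str] | None,
    config: FilterConfig | None = None,
) -> Tuple[np.ndarray, CallableSummary, Dict[str, np.ndarray]]:
    """Run the filter chain; returns (callable mask, stage summary, per-filter
    fail arrays).  Sites must be sorted by (chrom, pos)."""
    config = config or FilterConfig()
    if not dataset.is_sorted():
        raise ValueError("sites must be sorted by (chrom, pos)")
    fails = evaluate_filters(dataset, repeat_mask, reference, config)
    surviving = np.ones(dataset.n_sites, dtype=bool)
    summary = CallableSummary(n_input=dataset.n_sites)
    for name in FILTER_ORDER:
        if name == "gc" and not config.gc_filter_enabled:
            continue
        surviving &= ~fails[name]
        summary.stage_counts.append((name, int(surviving.sum())))
    summary.validate_monotone()
    return surviving, summary, fails


def count_callable(
    dataset: TrioDataset,
    repeat_mask: RepeatMask | None,
    reference: Mapping[str, str] | None,
    config: FilterConfig | None = None,
) -> CallableSummary:
    """Per-stage surviving counts; the final count is the callable-genome
    size L for this trio."""
    _, summary, _ = apply_filters(dataset, repeat_mask, reference, config)
    return summary


def estimate_filter_fraction_by_sampling(
    dataset: TrioDataset,
    filter_name: str,
    n_sample: int,
    seed: int,
    repeat_mask: RepeatMask | None = None,
    reference: Mapping[str, str] | None = None,
    config: FilterConfig | None = None,
) -> Tuple[float, float, bool]:
    """Binomial estimate of the proportion of sites a single filter removes.

    Useful when a filter is too expensive to apply genome-wide.  Returns
    (proportion, standard error, exact) where ``exact`` is True when the whole
    stream was used because ``n_sample`` met or exceeded it.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if filter_name not in FILTER_ORDER:
        raise ValueError(f"unknown filter {filter_name!r}")
    config = config or FilterConfig()
    if filter_name != "gc":
        # evaluating a single non-GC filter must not demand a reference
        config = replace(config, gc_filter_enabled=False)
    elif not config.gc_filter_enabled:
        config = replace(config, gc_filter_enabled=True)
    fails = evaluate_filters(dataset, repeat_mask, reference, config)[filter_name]
    n = dataset.n_sites
    if n_sample >= n:
        p = float(fails.mean()) if n else 0.0
        return p, 0.0, True
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_sample, replace=False)
    p = float(fails[idx].mean())
    se = math.sqrt(p * (1.0 - p) / n_sample)
    return p, se, False
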