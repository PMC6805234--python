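"""End-to-end orchestration: filters -> candidates -> validation -> FNR ->
posterior, for one trio or a pooled set.

The run is two-phase, mirroring how pedigree studies actually proceed:
discovery produces a candidate report for independent validation (Sanger in
the original workflow); estimation resumes once a validation-status table is
available (or immediately, with ``assume_all_confirmed``, for fully
synthetic runs where no human step exists).  Every report carries a
provenance block (configuration hash, seeds, thresholds) sufficient to
reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .candidate_discovery import (
    MutationCountBounds,
    find_candidates,
    mutation_count_bounds,
    quality_background,
)
from .fnr_estimation import FnrEstimate, estimate_trio_fnr
from .genotype_model import PriorConfig
from .rate_posterior import (
    RatePosterior,
    TrioCallable,
    per_trio_estimate,
    point_estimate,
    posterior_params,
    rate_bounds,
)
from .site_filters import (
    CallableSummary,
    FilterConfig,
    RepeatMask,
    TrioDataset,
    apply_filters,
)

__all__ = [
    "PipelineConfig",
    "TrioResult",
    "MultiTrioReport",
    "run_trio",
    "run_multi_trio",
    "run_gc_scenarios",
]


@dataclass
class PipelineConfig:
    """Configuration for a pipeline run; study defaults baked in."""

    filter_config: FilterConfig = field(default_factory=FilterConfig)
    prior_config: PriorConfig = field(default_factory=PriorConfig)
    fnr_n_planted: int = 10_000
    seed: int = 0
    posterior_quantiles: Tuple[float, float] = (0.05, 0.95)
    assume_all_confirmed: bool = False

    def provenance(self) -> Dict:
        blob = {
            "filter_config": asdict(self.filter_config),
            "prior_config": asdict(self.prior_config),
            "fnr_n_planted": self.fnr_n_planted,
            "seed": self.seed,
            "posterior_quantiles": list(self.posterior_quantiles),
            "assume_all_confirmed": self.assume_all_confirmed,
        }
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": blob, "config_hash": digest}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "filter_config" in raw:
            kwargs["filter_config"] = FilterConfig(**raw["filter_config"])
        if "prior_config" in raw:
            kwargs["prior_config"] = PriorConfig(**raw["prior_config"])
        for key in ("fnr_n_planted", "seed", "assume_all_confirmed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "posterior_quantiles" in raw:
            kwargs["posterior_quantiles"] = tuple(raw["posterior_quantiles"])
        return cls(**kwargs)


@dataclass
class TrioResult:
    """Everything one trio contributes to the pooled rate model."""

    trio_id: str
    summary: CallableSummary
    callable_mask: np.ndarray
    candidates: pd.DataFrame            # annotated candidate report
    fnr: Optional[FnrEstimate]
    bounds: Optional[MutationCountBounds]
    awaiting_validation: bool = False
    provenance: Dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.summary.callable_count

    def trio_callable(self, x: int) -> TrioCallable:
        if self.fnr is None:
            raise ValueError("FNR has not been estimated for this trio")
        return TrioCallable(
            trio_id=self.trio_id, L=self.L, beta=self.fnr.overall_beta, x=x
        )


def _active_stages(config: "PipelineConfig"):
    from .site_filters import FILTER_ORDER

    return [
        n
        for n in FILTER_ORDER
        if n != "gc" or config.filter_config.gc_filter_enabled
    ]


def run_trio(
    dataset: TrioDataset,
    repeat_mask: Optional[RepeatMask],
    reference: Optional[Mapping[str, str]],
    config: Optional[PipelineConfig] = None,
    trio_id: str = "trio",
    validation: Optional[pd.DataFrame] = None,
) -> TrioResult:
    """Run one trio through filters, candidate discovery and (when validation
    statuses are available) FNR estimation and count bounding.

    With neither ``validation`` nor ``assume_all_confirmed``, the run stops
    after the candidate report with ``awaiting_validation=True``.
    """
    config = config or PipelineConfig()
    if dataset.n_sites == 0:
        return TrioResult(
            trio_id=trio_id,
            summary=CallableSummary(
                n_input=0, stage_counts=[(n, 0) for n in _active_stages(config)]
            ),
            callable_mask=np.zeros(0, dtype=bool),
            candidates=find_candidates(dataset, np.zeros(0, dtype=bool)),
            fnr=None,
            bounds=MutationCountBounds(0, 0),
            provenance=config.provenance(),
        )
    callable_mask, summary, fails = apply_filters(
        dataset, repeat_mask, reference, config.filter_config
    )

    candidates = find_candidates(dataset, callable_mask, config.prior_config)
    if len(candidates) and callable_mask.any():
        try:
            background = quality_background(dataset, callable_mask)
            candidates = background.annotate(candidates)
        except ValueError:
            pass  # no conditioned background sites; report stays unannotated

    if validation is None and not config.assume_all_confirmed:
        return TrioResult(
            trio_id=trio_id,
            summary=summary,
            callable_mask=callable_mask,
            candidates=candidates,
            fnr=None,
            bounds=None,
            awaiting_validation=True,
            provenance=config.provenance(),
        )

    if validation is not None:
        bounds = mutation_count_bounds(validation)
    else:
        x = len(candidates)
        bounds = MutationCountBounds(x_min=x, x_max=x)

    fnr = estimate_trio_fnr(
        dataset,
        fails,
        callable_mask,
        config.prior_config,
        n_planted=config.fnr_n_planted,
        seed=config.seed,
    )
    return TrioResult(
        trio_id=trio_id,
        summary=summary,
        callable_mask=callable_mask,
        candidates=candidates,
        fnr=fnr,
        bounds=bounds,
        provenance=config.provenance(),
    )


@dataclass
class MultiTrioReport:
    """Pooled posterior summary over trios (one GC-filter scenario)."""

    posterior_min: RatePosterior
    posterior_max: RatePosterior
    rate_lower: float
    rate_upper: float
    per_trio_rates: Dict[str, Tuple[float, float]]  # trio -> (min, max) MLE
    x_min: int
    x_max: int
    total_site_generations: float
    provenance: Dict = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "total_site_generations": self.total_site_generations,
            "posterior_min": {"shape": self.posterior_min.shape, "rate": self.posterior_min.rate_param, "mean": self.posterior_min.mean},
            "posterior_max": {"shape": self.posterior_max.shape, "rate": self.posterior_max.rate_param, "mean": self.posterior_max.mean},
            "rate_lower": self.rate_lower,
            "rate_upper": self.rate_upper,
            "per_trio_rates": self.per_trio_rates,
            "provenance": self.provenance,
        }


def run_multi_trio(
    results: Sequence[TrioResult],
    config: Optional[PipelineConfig] = None,
) -> MultiTrioReport:
    """Pool completed trio results into the Poisson-Gamma rate model."""
    config = config or PipelineConfig()
    results = list(results)
    if not results:
        raise ValueError("need at least one trio result")
    if any(r.fnr is None or r.bounds is None for r in results):
        raise ValueError("all trio results must have FNR and mutation-count bounds")
    gc_settings = {
        r.provenance.get("config", {})
        .get("filter_config", {})
        .get("gc_filter_enabled")
        for r in results
    }
    if len(gc_settings) > 1:
        raise ValueError(
            "pooled trios were filtered with inconsistent GC-filter settings; "
            "scenarios must be coherent"
        )

    trios_min = [r.trio_callable(r.bounds.x_min) for r in results]
    trios_max = [r.trio_callable(r.bounds.x_max) for r in results]
    x_min = sum(r.bounds.x_min for r in results)
    x_max = sum(r.bounds.x_max for r in results)
    post_min = posterior_params(trios_min)
    post_max = posterior_params(trios_max)
    lower, upper = rate_bounds(x_min, x_max, trios_min, config.posterior_quantiles)
    per_trio = {
        r.trio_id: (
            per_trio_estimate(r.trio_callable(r.bounds.x_min)),
            per_trio_estimate(r.trio_callable(r.bounds.x_max)),
        )
        for r in results
    }
    return MultiTrioReport(
        posterior_min=post_min,
        posterior_max=post_max,
        rate_lower=lower,
        rate_upper=upper,
        per_trio_rates=per_trio,
        x_min=x_min,
        x_max=x_max,
        total_site_generations=post_min.rate_param,
        provenance=config.provenance(),
    )


def run_gc_scenarios(
    datasets: Sequence[TrioDataset],
    repeat_masks: Sequence[Optional[RepeatMask]],
    references: Sequence[Optional[Mapping[str, str]]],
    config: Optional[PipelineConfig] = None,
    trio_ids: Optional[Sequence[str]] = None,
    validations: Optional[Sequence[Optional[pd.DataFrame]]] = None,
) -> Dict:
    """Run the 2x2 scenario grid (GC filter on/off x min/max counts) and
    average the four posterior means into the point estimate."""
    config = config or PipelineConfig()
    n = len(datasets)
    trio_ids = list(trio_ids or (f"trio{i}" for i in range(n)))
    validations = list(validations or [None] * n)
    scenario_reports: Dict[str, MultiTrioReport] = {}
    posteriors: List[RatePosterior] = []
    for gc_on in (True, False):
        cfg = replace(
            config, filter_config=replace(config.filter_config, gc_filter_enabled=gc_on)
        )
        results = [
            run_trio(ds, rm, ref, cfg, trio_id=tid, validation=val)
            for ds, rm, ref, tid, val in zip(
                datasets, repeat_masks, references, trio_ids, validations
            )
        ]
        report = run_multi_trio(results, cfg)
        scenario_reports["gc_on" if gc_on else "gc_off"] = report
        posteriors.extend([report.posterior_min, report.posterior_max])
    return {
        "scenarios": scenario_reports,
        "point_estimate": point_estimate(posteriors),
    }
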