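"""Filter-chain tests: planted violations against a per-site brute-force
oracle, plus the individual predicates."""

import math

import numpy as np
import pytest

from conftest import make_dataset, set_reads
from pedmut.genotype_model import HOMREF, ml_genotype
from pedmut.site_filters import (
    FILTER_ORDER,
    FilterConfig,
    RepeatMask,
    TrioSite,
    apply_filters,
    count_callable,
    estimate_filter_fraction_by_sampling,
    evaluate_filters,
    gc_fraction,
    site_filter_flags,
)

MOTHER, FATHER = 1, 2


# ---------------------------------------------------------------------------
# 1000-site fixture with known planted violations of every filter


def build_violation_fixture(seed=0):
    """Returns (dataset, repeat_mask, reference, planted) where planted maps
    filter name -> set of 1-based positions that violate it."""
    rng = np.random.default_rng(seed)
    n = 1000
    ds = make_dataset(n)
    planted = {}

    # reference: A/T everywhere except a GC-rich tract around sites 900-905
    seq = list("AT" * (n // 2))
    gc_sites = [900, 901, 902, 903, 904]
    for p in range(840, 966):
        seq[p - 1] = "G"
    reference = {"1": "".join(seq)}
    planted["gc"] = set(gc_sites)  # only these get tested below via oracle

    repeat_mask = RepeatMask({"1": [(99, 110), (499, 500)]})  # 0-based half-open
    planted["repeat"] = set(range(100, 111)) | {500}

    planted["depth"] = {50, 51, 52}
    ds.depth[49, MOTHER] = 9
    set_reads(ds, 50, 0, 101, 0)
    ds.depth[51, FATHER] = 5

    planted["missing"] = {60, 61}
    ds.depth[59, 0] = 0
    ds.deletion_read_fraction[60] = 0.06

    planted["parental_alt"] = {70, 71}
    set_reads(ds, 69, MOTHER, 30, 1)
    set_reads(ds, 70, FATHER, 30, 2)

    planted["gap"] = {80, 81}
    ds.gap_read_count[79] = 3
    ds.gap_read_count[80] = 7

    # density cluster: 5 het-called sites at 200..204 -> each of them sees 4
    # variant neighbors, and nearby non-variant sites see >= 4 too
    for p in (200, 201, 202, 203, 204):
        set_reads(ds, p - 1, 0, 30, 15)
    return ds, repeat_mask, reference, planted


def oracle_fail_sets(ds, repeat_mask, reference, config):
    """Independent per-site evaluation of every filter (quadratic density
    scan, per-site python logic)."""
    n = ds.n_sites
    seq = reference["1"]
    # variant call per site: any individual's MAP genotype (likelihood plus
    # heterozygosity log-prior) non-hom-ref
    th = config.density_call_theta
    lp = np.log([1 - th - th * th / 4, th, th * th / 4])
    variant = [
        any(int(np.argmax(ds.gl[i, j] + lp)) != HOMREF for j in range(3))
        for i in range(n)
    ]
    fails = {name: set() for name in FILTER_ORDER}
    for i in range(n):
        pos = int(ds.pos[i])
        if bool(repeat_mask.contains("1", [pos])[0]):
            fails["repeat"].add(pos)
        if any(ds.depth[i, j] == 0 for j in range(3)) or ds.deletion_read_fraction[i] > config.deletion_fraction_max:
            fails["missing"].add(pos)
        if any(
            ds.depth[i, j] < config.depth_min or ds.depth[i, j] > config.depth_max
            for j in range(3)
        ):
            fails["depth"].add(pos)
        if ds.alt_count[i, MOTHER] >= 1 or ds.alt_count[i, FATHER] >= 1:
            fails["parental_alt"].add(pos)
        neighbors = sum(
            1
            for k in range(n)
            if k != i
            and variant[k]
            and abs(int(ds.pos[k]) - pos) <= config.density_window
        )
        if neighbors > config.density_max_variants:
            fails["density"].add(pos)
        if ds.gap_read_count[i] > config.gap_reads_max:
            fails["gap"].add(pos)
        half = config.gc_window // 2
        lo = max(pos - half, 1)
        hi = min(pos + half, len(seq))
        window = seq[lo - 1 : pos - 1] + seq[pos:hi]
        frac = gc_fraction(window)
        if math.isnan(frac) or frac > config.gc_max:
            fails["gc"].add(pos)
    return fails


@pytest.fixture(scope="module")
def violation_fixture():
    return build_violation_fixture()


class TestFilterChain:
    def test_planted_violations_match_per_site_oracle(self, violation_fixture):
        ds, mask, ref, planted = violation_fixture
        config = FilterConfig()
        fails = evaluate_filters(ds, mask, ref, config)
        oracle = oracle_fail_sets(ds, mask, ref, config)
        for name in FILTER_ORDER:
            got = set(int(p) for p in ds.pos[fails[name]])
            assert got == oracle[name], f"filter {name} disagrees with oracle"
        # the planted sets are contained in the oracle sets
        for name, sites in planted.items():
            assert sites <= oracle[name]

    def test_callable_set_matches_oracle(self, violation_fixture):
        ds, mask, ref, _ = violation_fixture
        config = FilterConfig()
        callable_mask, summary, _ = apply_filters(ds, mask, ref, config)
        oracle = oracle_fail_sets(ds, mask, ref, config)
        bad = set().union(*oracle.values())
        expected = {int(p) for p in ds.pos} - bad
        got = {int(p) for p in ds.pos[callable_mask]}
        assert got == expected
        assert summary.callable_count == len(expected)

    def test_stage_counts_are_non_increasing(self, violation_fixture):
        ds, mask, ref, _ = violation_fixture
        summary = count_callable(ds, mask, ref)
        counts = [summary.n_input] + [c for _, c in summary.stage_counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_final_set_is_order_independent(self, violation_fixture):
        ds, mask, ref, _ = violation_fixture
        fails = evaluate_filters(ds, mask, ref, FilterConfig())
        order_a = list(FILTER_ORDER)
        order_b = list(reversed(FILTER_ORDER))
        surv_a = np.ones(ds.n_sites, dtype=bool)
        surv_b = np.ones(ds.n_sites, dtype=bool)
        for name in order_a:
            surv_a &= ~fails[name]
        for name in order_b:
            surv_b &= ~fails[name]
        np.testing.assert_array_equal(surv_a, surv_b)

    def test_gc_toggle_changes_count_by_planted_gc_failures(self):
        # 50 GC-failing sites that pass everything else
        n = 1000
        ds = make_dataset(n)
        seq = list("AT" * (n // 2))
        for p in range(700, 751):  # make sites 701..750 sit in GC-rich context
            pass
        for p in range(640, 811):
            seq[p - 1] = "C"
        reference = {"1": "".join(seq)}
        cfg_on = FilterConfig(gc_filter_enabled=True)
        cfg_off = FilterConfig(gc_filter_enabled=False)
        on = count_callable(ds, None, reference, cfg_on)
        off = count_callable(ds, None, reference, cfg_off)
        fails = evaluate_filters(ds, None, reference, cfg_on)
        n_gc = int(fails["gc"].sum())
        assert n_gc > 0
        assert off.callable_count - on.callable_count == n_gc

    def test_empty_stream_counts_all_zero(self):
        ds = make_dataset(0)
        summary = count_callable(ds, None, {"1": ""})
        assert summary.n_input == 0
        assert all(c == 0 for _, c in summary.stage_counts)

    def test_unsorted_input_raises(self):
        ds = make_dataset(10)
        ds.pos = ds.pos[::-1].copy()
        with pytest.raises(ValueError, match="sorted"):
            count_callable(ds, None, {"1": "A" * 100})

    def test_gc_filter_without_reference_raises(self):
        ds = make_dataset(5)
        with pytest.raises(ValueError, match="reference"):
            evaluate_filters(ds, None, None, FilterConfig(gc_filter_enabled=True))


class TestSiteFlags:
    def _clean_site(self, **kwargs):
        from pedmut.genotype_model import genotype_likelihood_from_reads

        gl = genotype_likelihood_from_reads(30, 0, 0.01)
        defaults = dict(
            chrom="1",
            pos=500,
            ref="A",
            alt="G",
            depths=(30, 30, 30),
            alt_counts=(0, 0, 0),
            gls=(gl, gl, gl),
            qd=15.0,
            mq_rank_sum=0.0,
            gap_read_count=0,
            deletion_read_fraction=0.0,
        )
        defaults.update(kwargs)
        return TrioSite(**defaults)

    def test_low_mother_depth_flags_depth_only(self):
        site = self._clean_site(depths=(30, 9, 30))
        flags = site_filter_flags(site, reference_context="AT" * 50)
        assert flags == {"depth"}

    def test_three_gap_reads_flag_gap(self):
        site = self._clean_site(gap_read_count=3)
        assert site_filter_flags(site, reference_context="AT" * 50) == {"gap"}

    def test_clean_site_is_callable(self):
        site = self._clean_site()
        ctx = "ATGC" * 25  # 50% GC, below the 60% cutoff
        assert site_filter_flags(site, reference_context=ctx) == set()

    def test_parental_alt_read_flags(self):
        site = self._clean_site(alt_counts=(0, 1, 0))
        assert "parental_alt" in site_filter_flags(site, reference_context="AT" * 50)

    def test_gc_context_required_when_enabled(self):
        with pytest.raises(ValueError):
            site_filter_flags(self._clean_site())
        assert site_filter_flags(
            self._clean_site(), config=FilterConfig(gc_filter_enabled=False)
        ) == set()


class TestGcFraction:
    def test_pure_gc_window(self):
        assert gc_fraction("GGGGCCCC") == 1.0

    def test_61_percent_fails_at_cutoff(self):
        window = "G" * 61 + "A" * 39
        frac = gc_fraction(window)
        assert frac == pytest.approx(0.61)
        assert frac > FilterConfig().gc_max

    def test_ambiguous_bases_excluded(self):
        # 3 G/C among 8 unambiguous bases, plus 2 Ns
        window = "GCGATTAANN"[:10]
        assert gc_fraction(window) == pytest.approx(3 / 8)

    def test_all_ambiguous_is_undefined(self):
        assert math.isnan(gc_fraction("NNNN"))


class TestSamplingEstimator:
    @pytest.fixture()
    def ten_percent_gap_fixture(self):
        ds = make_dataset(2000)
        ds.gap_read_count[:200] = 5  # exactly 10% fail the gap filter
        return ds

    def test_filter_failing_nothing_is_zero(self):
        ds = make_dataset(100)
        p, se, exact = estimate_filter_fraction_by_sampling(ds, "gap", 1000, seed=1)
        assert (p, se, exact) == (0.0, 0.0, True)

    def test_exhaustive_sample_is_exact(self, ten_percent_gap_fixture):
        p, se, exact = estimate_filter_fraction_by_sampling(
            ten_percent_gap_fixture, "gap", 10_000, seed=1
        )
        assert p == pytest.approx(0.10)
        assert exact

    def test_subsample_within_three_se(self, ten_percent_gap_fixture):
        p, se, exact = estimate_filter_fraction_by_sampling(
            ten_percent_gap_fixture, "gap", 1000, seed=2
        )
        assert not exact
        assert se == pytest.approx(math.sqrt(p * (1 - p) / 1000))
        assert abs(p - 0.10) <= 3 * math.sqrt(0.1 * 0.9 / 1000)

    def test_unknown_filter_raises(self, ten_percent_gap_fixture):
        with pytest.raises(ValueError):
            estimate_filter_fraction_by_sampling(ten_percent_gap_fixture, "bogus", 10, 0)
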