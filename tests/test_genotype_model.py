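"""Unit and property tests for the trio genotype model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedmut.genotype_model import (
    GenotypeLikelihoods,
    PriorConfig,
    dn_score,
    dn_score_array,
    genotype_likelihood_from_reads,
    genotype_likelihoods_from_read_arrays,
    gl_field_to_loglik,
    log_config_prior,
    parental_pair_prior,
    pl_to_loglik,
    transmission_prob,
)

from conftest import oracle_dn_score, oracle_transmission, random_gl_triples


class TestTransmission:
    def test_mendelian_certainty_without_mutation(self):
        assert transmission_prob("homref", "homref", "homref", 0.0) == 1.0
        assert transmission_prob("het", "homref", "homref", 0.0) == 0.0

    def test_dnm_configuration_probability_matches_enumeration(self):
        mu = 1e-6
        got = transmission_prob("het", "homref", "homref", mu)
        expected = oracle_transmission(1, 0, 0, mu)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2 * mu * (1 - mu), rel=1e-9)

    @pytest.mark.parametrize("mu", [0.0, 1e-6, 0.01, 0.3])
    @pytest.mark.parametrize("mother", [0, 1, 2])
    @pytest.mark.parametrize("father", [0, 1, 2])
    def test_sums_to_one_over_child_genotypes(self, mother, father, mu):
        total = sum(transmission_prob(c, mother, father, mu) for c in range(3))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mu", [0.0, 1e-4, 0.2])
    def test_matches_gamete_enumeration_everywhere(self, mu):
        for c in range(3):
            for m in range(3):
                for f in range(3):
                    assert transmission_prob(c, m, f, mu) == pytest.approx(
                        oracle_transmission(c, m, f, mu), abs=1e-14
                    )

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            transmission_prob("hemizygous", "homref", "homref", 0.0)
        with pytest.raises(ValueError):
            transmission_prob("het", "homref", "homref", 1.0)
        with pytest.raises(ValueError):
            transmission_prob("het", "homref", "homref", -0.1)


class TestParentalPairPrior:
    def test_normalizes_over_nine_pairs(self):
        total = sum(
            parental_pair_prior(m, f, 0.008) for m in range(3) for f in range(3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_homref_pair_closed_form(self):
        theta = 0.008
        expected = (1 - theta - theta**2 / 4) ** 2
        assert parental_pair_prior(0, 0, theta) == pytest.approx(expected, rel=1e-14)
        # cross-check against the summed complement
        complement = sum(
            parental_pair_prior(m, f, theta)
            for m in range(3)
            for f in range(3)
            if (m, f) != (0, 0)
        )
        assert parental_pair_prior(0, 0, theta) == pytest.approx(
            1.0 - complement, abs=1e-12
        )

    def test_default_theta_is_liberal_scoring_prior(self):
        assert PriorConfig().theta == 0.008
        assert PriorConfig().mu_prior == 1.0e-6

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_theta_raises(self, theta):
        with pytest.raises(ValueError):
            parental_pair_prior(0, 0, theta)


class TestDnScore:
    def test_config_prior_normalizes(self):
        lp = log_config_prior(PriorConfig())
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_alt_evidence_scores_negligibly(self):
        homref = [0.0, -200.0, -400.0]
        assert dn_score(homref, homref, homref) < 1e-10

    def test_clear_dnm_scores_high(self):
        child = genotype_likelihood_from_reads(15, 15, 0.01)
        parent = genotype_likelihood_from_reads(30, 0, 0.01)
        assert dn_score(child, parent, parent) > 0.99

    def test_matches_bruteforce_enumeration_on_random_triples(self):
        rng = np.random.default_rng(42)
        prior = PriorConfig()
        c = random_gl_triples(rng, 200)
        m = random_gl_triples(rng, 200)
        f = random_gl_triples(rng, 200)
        scores = dn_score_array(c, m, f, prior)
        for i in range(200):
            expected = oracle_dn_score(c[i], m[i], f[i], prior.mu_prior, prior.theta)
            assert abs(scores[i] - expected) < 1e-12

    def test_invariant_to_per_individual_likelihood_offsets(self):
        rng = np.random.default_rng(7)
        c, m, f = (random_gl_triples(rng, 50) for _ in range(3))
        base = dn_score_array(c, m, f)
        shifted = dn_score_array(c + 17.0, m - 5.0, f + 2.5)
        np.testing.assert_allclose(shifted, base, rtol=1e-10)

    def test_monotone_in_mu_prior_within_dnm_evidence_regime(self):
        # offspring maximum-likelihood het (the DNM signature); in this
        # regime the DNM configuration's prior mass grows linearly in mu
        # while all competing mass grows no faster
        rng = np.random.default_rng(3)
        cases = []
        for _ in range(50):
            d = int(rng.integers(10, 40))
            alt = int(rng.integers(max(1, d // 4), 3 * d // 4 + 1))
            child = genotype_likelihood_from_reads(d - alt, alt, 0.01).as_array()
            if np.argmax(child) != 1:
                continue
            dp = int(rng.integers(10, 40))
            mother = genotype_likelihood_from_reads(dp, int(rng.integers(0, 2)), 0.01)
            father = genotype_likelihood_from_reads(dp, 0, 0.01)
            cases.append((child, mother.as_array(), father.as_array()))
        assert cases
        for child, mother, father in cases:
            scores = [
                dn_score(child, mother, father, PriorConfig(mu_prior=mu))
                for mu in (1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
            ]
            assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_vanishes_as_mu_prior_goes_to_zero(self):
        child = genotype_likelihood_from_reads(15, 15, 0.01)
        parent = genotype_likelihood_from_reads(30, 0, 0.01)
        tiny = dn_score(child, parent, parent, PriorConfig(mu_prior=1e-300))
        assert tiny < 1e-250

    @given(
        st.lists(st.floats(min_value=-50, max_value=0), min_size=9, max_size=9),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_is_a_probability(self, values):
        c, m, f = np.array(values[:3]), np.array(values[3:6]), np.array(values[6:])
        s = dn_score(c, m, f)
        assert 0.0 <= s <= 1.0

    def test_uninformative_likelihoods_fall_back_to_prior(self):
        flat = [0.0, 0.0, 0.0]
        s = dn_score(flat, flat, flat)
        prior = PriorConfig()
        lp = log_config_prior(prior)
        assert s == pytest.approx(float(np.exp(lp[1, 0, 0])), rel=1e-9)
        assert GenotypeLikelihoods.from_array(flat).is_uninformative


class TestReadModel:
    def test_no_reads_is_uninformative(self):
        gl = genotype_likelihood_from_reads(0, 0, 0.01)
        assert gl.is_uninformative

    def test_balanced_reads_favor_het(self):
        gl = genotype_likelihood_from_reads(5, 5, 0.01).as_array()
        assert np.argmax(gl) == 1

    def test_matches_per_read_product_oracle(self):
        e = 0.01
        gl = genotype_likelihood_from_reads(10, 0, e).as_array()
        # direct per-read products, computed independently
        p_alt = [e, 0.5, 1 - e]
        raw = [10 * math.log(1 - p) for p in p_alt]
        expected = np.array(raw) - max(raw)
        np.testing.assert_allclose(gl, expected, atol=1e-12)

    def test_vectorized_and_scalar_agree(self):
        ref = np.array([3, 0, 20])
        alt = np.array([1, 0, 5])
        mat = genotype_likelihoods_from_read_arrays(ref, alt, 0.02)
        for i in range(3):
            single = genotype_likelihood_from_reads(int(ref[i]), int(alt[i]), 0.02)
            np.testing.assert_allclose(mat[i], single.as_array(), atol=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            genotype_likelihood_from_reads(-1, 0, 0.01)
        with pytest.raises(ValueError):
            genotype_likelihood_from_reads(1, 1, 0.0)


class TestLikelihoodEncodings:
    def test_pl_conversion_is_exact(self):
        pl = [0, 30, 300]
        expected = -np.array(pl) * math.log(10.0) / 10.0
        np.testing.assert_array_equal(pl_to_loglik(pl), expected)

    def test_gl_conversion_normalizes(self):
        gl10 = [-0.3, -0.1, -5.0]
        out = gl_field_to_loglik(gl10)
        assert out.max() == 0.0
        np.testing.assert_allclose(
            out, np.array(gl10) * math.log(10.0) + 0.1 * math.log(10.0), atol=1e-12
        )

    def test_triple_classmethods_agree(self):
        pl = [10, 0, 42]
        a = GenotypeLikelihoods.from_pl(pl).as_array()
        b = GenotypeLikelihoods.from_array(pl_to_loglik(pl)).as_array()
        np.testing.assert_array_equal(a, b)

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError):
            GenotypeLikelihoods.from_array([0.0, -1.0])
        with pytest.raises(ValueError):
            GenotypeLikelihoods.from_array([0.0, -1.0, float("nan")])
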