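import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_linear_activation_positive, make_linear_inactivation_negative
from fbnoise.analytic import (
    AnalyticError,
    SteadyStateDistribution,
    TruncationError,
    decompose_noise,
    distribution_moments,
    efficiency,
    feedback_coefficient_exact,
    negative_binomial_pmf,
    noise_bounds_negative,
    steady_state_distribution,
    tail_decay_check,
)
from fbnoise.kinetics import (
    BurstParameters,
    hill_regulatory_function,
    hill_steepness,
    regulatory_from_config,
)


def constant_c(value):
    return regulatory_from_config({"form": "constant", "c": float(value)})


def bursts_for(p, lam=30.0):
    return BurstParameters(p=p, q=1.0 - p, lam=lam)


class TestSteadyStateDistribution:
    def test_matches_negative_binomial_elementwise(self, rng):
        for _ in range(10):
            c = rng.uniform(0.5, 300.0)
            d = rng.uniform(0.5, 3.0)
            p = rng.uniform(0.05, 0.98)
            prod = steady_state_distribution(constant_c(c), p=p, d=d)
            closed = negative_binomial_pmf(c, d, p)
            n = min(prod.probs.size, closed.probs.size)
            usable = prod.log_probs[:n] > -690
            np.testing.assert_allclose(
                prod.log_probs[:n][usable], closed.log_probs[:n][usable],
                atol=1e-12, rtol=0,
            )

    def test_zero_rate_gives_point_mass(self):
        dist = steady_state_distribution(constant_c(0.0), p=0.5, d=1.0)
        assert dist.probs[0] == pytest.approx(1.0)
        assert np.all(dist.probs[1:] == 0.0)

    def test_mean_matches_closed_form(self):
        # mean = (c/d)(p/q) for the no-feedback law
        dist = steady_state_distribution(constant_c(5.0), p=0.5, d=1.0)
        mean, var = distribution_moments(dist)
        assert mean == pytest.approx(5.0, rel=1e-10)
        assert var == pytest.approx(10.0, rel=1e-10)

    def test_truncation_mass_recorded_and_small(self, hill_negative):
        dist = steady_state_distribution(hill_negative, p=0.7, d=1.0, tail_tol=1e-12)
        assert 0.0 <= dist.truncation_mass <= 1e-12
        assert dist.probs.sum() + dist.truncation_mass == pytest.approx(1.0, abs=1e-10)

    def test_hard_cap_raises(self):
        with pytest.raises(TruncationError):
            steady_state_distribution(constant_c(50.0), p=0.999, d=0.01, n_cap=512)

    def test_invalid_p_rejected(self):
        with pytest.raises(AnalyticError):
            steady_state_distribution(constant_c(1.0), p=1.0, d=1.0)

    @given(
        a=st.floats(1.0, 500.0),
        s=st.floats(10.0, 200.0),
        r=st.floats(0.0, 10.0),
        h=st.floats(1.0, 4.0),
        p=st.floats(0.05, 0.95),
    )
    @settings(max_examples=25, deadline=None)
    def test_normalization_property(self, a, s, r, h, p):
        c = hill_regulatory_function(a=a, s=s, r=r, h=h)
        dist = steady_state_distribution(c, p=p, d=1.0)
        assert dist.probs.sum() + dist.truncation_mass == pytest.approx(1.0, abs=1e-10)
        assert np.all(dist.probs >= 0.0)


class TestNegativeBinomialPmf:
    def test_geometric_special_case(self):
        # c/d = 1 gives p_n = q p^n
        dist = negative_binomial_pmf(1.0, 1.0, 0.5)
        n = np.arange(dist.probs.size)
        np.testing.assert_allclose(dist.probs, 0.5 * 0.5**n, rtol=1e-12)

    def test_p0_is_q_to_cd(self):
        dist = negative_binomial_pmf(3.0, 1.0, 0.6)
        assert dist.probs[0] == pytest.approx(0.4**3, rel=1e-12)

    def test_direct_arithmetic(self):
        # n = 2: (0.36/2) * (3*4) * 0.4^3 = 0.13824
        dist = negative_binomial_pmf(3.0, 1.0, 0.6)
        assert dist.probs[2] == pytest.approx(0.13824, rel=1e-12)

    def test_zero_rate(self):
        dist = negative_binomial_pmf(0.0, 1.0, 0.5)
        assert dist.probs.tolist() == [1.0]


class TestDistributionMoments:
    def test_point_mass(self):
        dist = SteadyStateDistribution(
            probs=np.array([1.0]), truncation_mass=0.0, source="analytic"
        )
        assert distribution_moments(dist) == (0.0, 0.0)

    def test_geometric_moments(self):
        # tolerance limited by the 1e-12 truncated tail mass, not arithmetic
        dist = negative_binomial_pmf(1.0, 1.0, 0.5)
        mean, var = distribution_moments(dist)
        assert mean == pytest.approx(1.0, rel=1e-8)
        assert var == pytest.approx(2.0, rel=1e-8)

    def test_negative_binomial_moments(self):
        dist = negative_binomial_pmf(2.0, 1.0, 0.5)
        mean, var = distribution_moments(dist)
        assert mean == pytest.approx(2.0, rel=1e-8)
        assert var == pytest.approx(4.0, rel=1e-8)

    def test_degenerate_rejected(self):
        dist = SteadyStateDistribution(
            probs=np.array([1.0]), truncation_mass=0.0, source="analytic"
        )
        dist.probs = np.array([0.0])
        with pytest.raises(AnalyticError):
            distribution_moments(dist)


class TestFeedbackCoefficient:
    def test_constant_gives_zero(self):
        dist = steady_state_distribution(constant_c(8.0), p=0.6, d=1.0)
        assert feedback_coefficient_exact(dist, constant_c(8.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_increasing_c_gives_positive(self):
        c = make_linear_activation_positive(a=1.0, b=50.0, s=30.0, r=2.0)
        dist = steady_state_distribution(c, p=0.5, d=1.0)
        assert feedback_coefficient_exact(dist, c) > 0.0

    def test_matches_decomposition_identity(self):
        c = hill_regulatory_function(a=50.0, s=100.0, r=5.0, h=2.0)
        p = 0.7
        dist = steady_state_distribution(c, p=p, d=1.0)
        mean, var = distribution_moments(dist)
        eta = var / mean**2
        eta_f = feedback_coefficient_exact(dist, c)
        assert eta_f < 0.0
        assert eta_f == pytest.approx(eta - 1.0 / ((1.0 - p) * mean), abs=1e-10)


class TestDecomposeNoise:
    def test_no_feedback_identities(self):
        p = 0.6
        dist = steady_state_distribution(constant_c(10.0), p=p, d=1.0)
        dec = decompose_noise(dist, constant_c(10.0), bursts_for(p), d=1.0, v=30.0)
        assert dec.eta_f == pytest.approx(0.0, abs=1e-12)
        assert dec.eta == pytest.approx(dec.feedback_free, abs=1e-10)
        assert dec.eta_s is None

    def test_positive_feedback_super_poissonian(self):
        c = make_linear_activation_positive(a=1.0, b=50.0, s=30.0, r=2.0)
        dist = steady_state_distribution(c, p=0.5, d=1.0)
        dec = decompose_noise(dist, c, bursts_for(0.5), d=1.0, v=30.0)
        assert dec.eta_f > 0.0
        assert dec.eta > dec.feedback_free > dec.poisson_term

    def test_two_and_three_term_forms_agree(self, hill_negative):
        p = 0.7
        dist = steady_state_distribution(hill_negative, p=p, d=1.0)
        dec = decompose_noise(dist, hill_negative, bursts_for(p), d=1.0, v=30.0)
        assert dec.poisson_term + dec.mrna_term == pytest.approx(
            dec.feedback_free, abs=1e-10
        )
        assert dec.eta == pytest.approx(dec.feedback_free + dec.eta_f, abs=1e-10)

    def test_sub_poissonian_negative_feedback_exists(self):
        # steep repression (alpha >> d) pushes the noise below 1/<n>
        c = hill_regulatory_function(a=1500.0, s=450.0, r=1.0, h=3.5)
        dist = steady_state_distribution(c, p=0.3, d=1.0)
        dec = decompose_noise(dist, c, bursts_for(0.3), d=1.0, v=30.0)
        assert hill_steepness(1500.0, 450.0, 1.0, 3.5) > 1.0
        assert dec.eta < dec.poisson_term

    def test_empirical_source_gets_eta_s(self):
        p = 0.6
        ref = steady_state_distribution(constant_c(10.0), p=p, d=1.0)
        emp = SteadyStateDistribution(
            probs=ref.probs.copy(), truncation_mass=ref.truncation_mass,
            source="empirical_simulation",
        )
        dec = decompose_noise(emp, constant_c(10.0), bursts_for(p), d=1.0, v=30.0)
        assert dec.eta_s == pytest.approx(0.0, abs=1e-10)

    @given(
        a=st.floats(5.0, 500.0),
        s=st.floats(20.0, 200.0),
        r=st.floats(0.0, 10.0),
        h=st.floats(1.0, 4.0),
        p=st.floats(0.1, 0.9),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_decomposition_property(self, a, s, r, h, p):
        c = hill_regulatory_function(a=a, s=s, r=r, h=h)
        dist = steady_state_distribution(c, p=p, d=1.0)
        dec = decompose_noise(dist, c, bursts_for(p), d=1.0, v=30.0)
        assert dec.eta == pytest.approx(dec.feedback_free + dec.eta_f, abs=1e-10)
        assert dec.eta > 0.0


class TestNoiseBounds:
    def test_alpha_zero_collapses(self):
        with pytest.warns(UserWarning):
            b = noise_bounds_negative(q=0.5, mean_n=10.0, alpha=0.0, p=0.5, d=1.0)
        assert b.lower == b.upper
        assert b.efficiency_cap == 0.0

    def test_unit_ratio_halves(self):
        # alpha p / (d q) = 1  ->  lower = upper / 2, cap = 1/2
        b = noise_bounds_negative(q=0.5, mean_n=10.0, alpha=1.0, p=0.5, d=1.0)
        assert b.lower == pytest.approx(b.upper / 2.0)
        assert b.efficiency_cap == pytest.approx(0.5)

    def test_exact_noise_within_bounds_randomized(self, rng):
        # small randomized version of the full acceptance sweep
        for _ in range(25):
            a = rng.uniform(5.0, 1000.0)
            r = rng.uniform(0.0, 5.0)
            s = r + rng.uniform(5.0, 300.0)
            h = rng.uniform(1.0, 4.0)
            p = rng.uniform(0.1, 0.9)
            c = hill_regulatory_function(a=a, s=s, r=r, h=h)
            dist = steady_state_distribution(c, p=p, d=1.0)
            mean, var = distribution_moments(dist)
            eta = var / mean**2
            alpha = hill_steepness(a, s, r, h)
            b = noise_bounds_negative(q=1.0 - p, mean_n=mean, alpha=alpha, p=p, d=1.0)
            assert b.lower - 1e-12 <= eta < b.upper
            eta_f = feedback_coefficient_exact(dist, c)
            if eta_f < 0:
                assert efficiency(eta, eta_f) <= b.efficiency_cap + 1e-12


class TestEfficiency:
    def test_printed_worked_example(self):
        # feedback-free noise 0.49, feedback coefficient -0.18 -> 36.7%
        gamma = efficiency(eta=0.49 - 0.18, eta_f=-0.18)
        assert round(100.0 * gamma, 1) == 36.7

    def test_two_parameterizations_agree(self):
        assert efficiency(0.31, -0.18) == pytest.approx(0.18 / 0.49, rel=1e-12)

    def test_vanishing_feedback(self):
        assert efficiency(0.5, -1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_domain_error_for_nonnegative_eta_f(self):
        with pytest.raises(AnalyticError):
            efficiency(0.5, 0.1)


class TestTailDecay:
    def test_geometric_tail(self):
        dist = negative_binomial_pmf(1.0, 1.0, 0.99)
        q = 0.01
        assert tail_decay_check(dist, q) < 0.05 * q

    def test_saturated_hill_with_unit_basal(self):
        # c -> r = d so the prefactor is flat and the ratio converges to p
        c = hill_regulatory_function(a=50.0, s=10.0, r=1.0, h=2.0)
        dist = steady_state_distribution(c, p=0.99, d=1.0)
        assert tail_decay_check(dist, 0.01) < 0.05 * 0.01

    def test_moderate_p_still_converges(self):
        dist = negative_binomial_pmf(1.0, 1.0, 0.5)
        assert tail_decay_check(dist, 0.5) < 0.05 * 0.5

    def test_requires_log_probs(self):
        dist = SteadyStateDistribution(
            probs=np.array([0.5, 0.5]), truncation_mass=0.0, source="empirical_data"
        )
        with pytest.raises(AnalyticError):
            tail_decay_check(dist, 0.1)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        dist = negative_binomial_pmf(2.0, 1.0, 0.5)
        path = tmp_path / "pmf.tsv"
        dist.to_tsv(path)
        data = np.loadtxt(path, skiprows=1)
        np.testing.assert_allclose(data[:, 1], dist.probs, rtol=1e-15)

    def test_decomposition_json(self, tmp_path):
        import json

        p = 0.6
        dist = steady_state_distribution(constant_c(10.0), p=p, d=1.0)
        dec = decompose_noise(dist, constant_c(10.0), bursts_for(p), d=1.0, v=30.0)
        payload = json.loads(dec.to_json(tmp_path / "dec.json"))
        assert payload["eta"] == pytest.approx(dec.eta)
        assert set(payload) >= {"eta", "poisson_term", "mrna_term",
                                "feedback_free", "eta_f", "mean_n", "var_n"}
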