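import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doseqa.errors import ParameterError
from doseqa.tg218_stats import (
    TG218Params,
    action_interval,
    beta_half_from_q,
    binomial_se,
    clipped_normal_moments,
    expected_fail_rate,
    match_clipped_normal,
    q_from_beta_half,
    sample_clipped_gpr,
    truncation_beta_correction,
)


class TestActionInterval:
    def test_zero_systematic_component(self):
        # the root collapses to the SD: A = (beta/2) * sigma
        lower, upper = action_interval(TG218Params(100, 100, 2, 6))
        assert lower == pytest.approx(94.0)
        assert upper == pytest.approx(106.0)

    def test_zero_random_component(self):
        lower, _ = action_interval(TG218Params(100, 98, 0, 6))
        assert lower == pytest.approx(94.0)

    def test_mixed_components(self):
        lower, upper = action_interval(TG218Params(100, 99, 1.5, 4))
        half = 2 * np.sqrt(2.25 + 1)
        assert half == pytest.approx(3.6056, abs=5e-5)
        assert lower == pytest.approx(100 - half)
        assert upper == pytest.approx(100 + half)

    def test_beta_must_be_positive(self):
        with pytest.raises(ParameterError):
            TG218Params(100, 99, 1, 0)


# printed conversion table: q -> beta/2 per sidedness; the 1.65 entries
# reflect the conventional 1.645 quantile (exact value 1.6449 rounds to 1.64)
PRINTED_ONE_SIDED = {0.02: 2.05, 0.05: 1.65, 0.1: 1.28, 0.2: 0.84}
PRINTED_TWO_SIDED = {0.02: 2.33, 0.05: 1.96, 0.1: 1.65, 0.2: 1.28}


class TestBetaHalfConversion:
    @pytest.mark.parametrize("q,expected", sorted(PRINTED_ONE_SIDED.items()))
    def test_one_sided_table(self, q, expected):
        assert beta_half_from_q(q, "one_sided") == pytest.approx(expected, abs=0.0055)

    @pytest.mark.parametrize("q,expected", sorted(PRINTED_TWO_SIDED.items()))
    def test_two_sided_table(self, q, expected):
        assert beta_half_from_q(q, "two_sided") == pytest.approx(expected, abs=0.0055)

    def test_exact_two_decimal_cells(self):
        assert round(beta_half_from_q(0.02, "one_sided"), 2) == 2.05
        assert round(beta_half_from_q(0.2, "one_sided"), 2) == 0.84
        assert round(beta_half_from_q(0.02, "two_sided"), 2) == 2.33
        assert round(beta_half_from_q(0.05, "two_sided"), 2) == 1.96

    def test_three_sigma_rates(self):
        assert round(q_from_beta_half(3, "two_sided"), 4) == 0.0027
        # exact value 0.00134990; the 0.0014 sometimes quoted comes from
        # rounding 0.0027/2 = 0.00135 upward, not from 1 - Phi(3) directly
        assert round(q_from_beta_half(3, "one_sided"), 4) == 0.0013
        assert q_from_beta_half(3, "one_sided") == pytest.approx(0.00135, abs=5.1e-5)

    def test_integer_sigma_anchor_cells(self):
        # the 3-sigma / 2-sigma columns anchor beta/2 and derive q from it
        assert round(q_from_beta_half(2, "one_sided"), 3) == 0.023
        assert round(q_from_beta_half(2, "two_sided"), 3) == 0.046
        # inverting the 2-significant-figure printed q recovers the anchors
        assert beta_half_from_q(0.023, "one_sided") == pytest.approx(2.0, abs=0.01)
        assert beta_half_from_q(0.0014, "one_sided") == pytest.approx(3.0, abs=0.02)
        assert beta_half_from_q(0.0027, "two_sided") == pytest.approx(3.0, abs=0.01)

    def test_median_is_zero(self):
        assert beta_half_from_q(0.5, "one_sided") == pytest.approx(0.0, abs=1e-12)

    def test_zero_beta_two_sided_everything_fails(self):
        assert q_from_beta_half(0, "two_sided") == 1.0

    @given(
        q=st.floats(1e-6, 0.5),  # b >= 0 domain: one-sided q above 0.5 maps negative
        sidedness=st.sampled_from(["one_sided", "two_sided"]),
    )
    @settings(max_examples=200)
    def test_exact_inverse(self, q, sidedness):
        assert q_from_beta_half(beta_half_from_q(q, sidedness), sidedness) == pytest.approx(
            q, abs=1e-10
        )

    def test_q_domain(self):
        with pytest.raises(ParameterError):
            beta_half_from_q(1.0, "one_sided")


class TestExpectedFailRate:
    def test_two_sided_printed_cell(self):
        # Normal(1.75, 2.41) beyond |4.5| -> 13% after integer rounding
        assert round(expected_fail_rate(1.75, 2.41, 4.5, "two_sided")) == 13

    def test_one_sided_symmetry(self):
        assert expected_fail_rate(95.0, 2.0, 95.0, "one_sided") == pytest.approx(50.0)

    def test_two_sided_wide_threshold_limit(self):
        assert expected_fail_rate(0.0, 1.0, 1e9, "two_sided") == pytest.approx(0.0)

    def test_degenerate_sd(self):
        assert expected_fail_rate(90.0, 0.0, 95.0, "one_sided") == 100.0
        assert expected_fail_rate(96.0, 0.0, 95.0, "one_sided") == 0.0
        assert expected_fail_rate(1.0, 0.0, 2.0, "two_sided") == 0.0


class TestBinomialSE:
    def test_maximum_variance(self):
        assert binomial_se(0.5, 100) == pytest.approx(5.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate(self, p):
        assert binomial_se(p, 50) == 0.0

    def test_thirteen_percent_cell(self):
        # full-precision SE for p = 0.13, n = 100 (the printed table rounds
        # from unrounded internal values)
        assert binomial_se(0.13, 100) == pytest.approx(3.363, abs=5e-4)


class TestClippedNormal:
    def test_moments_no_clipping(self):
        m, s = clipped_normal_moments(50.0, 2.0, bound=100.0)
        assert m == pytest.approx(50.0, abs=1e-9)
        assert s == pytest.approx(2.0, abs=1e-9)

    def test_moment_matching_round_trip(self):
        mu, sigma = match_clipped_normal(97.5, 1.5)
        m, s = clipped_normal_moments(mu, sigma)
        assert m == pytest.approx(97.5, abs=1e-6)
        assert s == pytest.approx(1.5, abs=1e-6)
        assert mu > 97.5 and sigma > 1.5  # clipping pulls both down

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ParameterError):
            match_clipped_normal(101.0, 1.0)

    def test_sample_moments(self):
        rng = np.random.default_rng(7)
        sample = sample_clipped_gpr(97.0, 2.0, 200_000, rng)
        assert sample.max() <= 100.0
        assert sample.mean() == pytest.approx(97.0, abs=0.02)
        assert sample.std(ddof=1) == pytest.approx(2.0, abs=0.02)


class TestTruncationCorrection:
    def test_far_from_bound_factor_near_one(self):
        factor = truncation_beta_correction(80.0, 2.0, 0.1, reps=50_000, seed=0)
        assert factor == pytest.approx(1.0, abs=0.03)

    def test_near_bound_factor_exceeds_one(self):
        factor = truncation_beta_correction(98.0, 1.4, 0.1, reps=50_000, seed=0)
        assert factor > 1.0

    def test_factor_non_decreasing_toward_bound(self):
        factors = [
            truncation_beta_correction(mean, 1.4, 0.05, reps=50_000, seed=11)
            for mean in (90.0, 96.0, 98.0, 99.0)
        ]
        assert all(b >= a - 0.01 for a, b in zip(factors, factors[1:]))

    def test_reps_floor(self):
        with pytest.raises(ParameterError):
            truncation_beta_correction(98.0, 1.4, 0.1, reps=100)

    def test_seed_reproducible(self):
        a = truncation_beta_correction(97.0, 1.5, 0.1, reps=20_000, seed=5)
        b = truncation_beta_correction(97.0, 1.5, 0.1, reps=20_000, seed=5)
        assert a == b
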