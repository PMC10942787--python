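"""Fano screen, intrinsic-Bayes-factor separability, and the combined gate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikemux.io import Triplet
from spikemux.screening import (ScreeningConfig, fano_factor, screen_triplet,
                                screen_triplets, separability_log_ibf,
                                separability_posterior)
from spikemux.simulate import RegimeSpec, simulate_population

from oracles import quad_log_ibf

# fixed samples drawn once from Poisson(20) and Poisson(2)
RATE20 = [22, 18, 19, 24, 20, 17, 21, 23, 19, 18]
RATE2 = [2, 1, 3, 2, 2, 1, 4, 2, 3, 1]


class TestFanoFactor:
    def test_zero_variance(self):
        assert fano_factor([3, 3, 3, 3]) == 0.0

    def test_direct_arithmetic(self):
        # mean 2, unbiased variance 4
        assert fano_factor([0, 2, 4]) == pytest.approx(2.0)

    def test_all_zero_counts_fail_screen(self):
        assert fano_factor([0, 0, 0]) == np.inf
        t = Triplet("u", "A|B", [0, 0, 0, 0, 0], RATE2[:5], RATE2[5:])
        assert "fano" in screen_triplet(t).failure_reasons

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            fano_factor([4])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 40), min_size=2, max_size=30), st.integers(1, 5))
    def test_appending_the_mean_never_increases_fano(self, counts, reps):
        mean = np.mean(counts)
        if mean == 0 or mean != int(mean):
            counts = counts + [int(np.ceil(mean)) or 1]  # force integer mean
            mean = np.mean(counts)
            if mean != int(mean):
                return
        before = fano_factor(counts)
        after = fano_factor(counts + [int(mean)] * reps)
        assert after <= before + 1e-12


class TestSeparability:
    def test_identical_samples_favor_shared_mean(self):
        assert separability_log_ibf([5] * 5, [5] * 5) < 0

    def test_well_separated_rates_pass_threshold(self):
        assert separability_log_ibf(RATE20, RATE2) > 3

    def test_symmetric_in_inputs(self):
        v1 = separability_log_ibf(RATE20, RATE2)
        v2 = separability_log_ibf(RATE2, RATE20)
        assert v1 == pytest.approx(v2, abs=1e-10)

    @pytest.mark.parametrize("a,b", [
        (RATE20, RATE2),
        ([6, 8, 7, 9, 5], [4, 5, 3, 6, 4]),
        ([0, 1, 0, 2, 1, 0], [3, 2, 4, 3, 5]),
        ([10] * 5, [10, 11, 9, 10, 12, 8]),  # unequal sample sizes
    ])
    def test_matches_quadrature_oracle(self, a, b):
        # the oracle assembles the same intrinsic Bayes factor from proper
        # Gamma(1/2, b0) priors with b0 -> 0 by adaptive quadrature
        oracle = quad_log_ibf(a, b, prior_rate=1e-8)
        assert separability_log_ibf(a, b) == pytest.approx(oracle, abs=2e-3)

    def test_threshold_of_3_implies_95pct_posterior(self):
        assert separability_posterior(3.0, prior_odds=1.0) > 0.95
        assert separability_posterior(3.0, prior_odds=1.0) == pytest.approx(
            np.exp(3) / (1 + np.exp(3)))

    def test_equal_rate_false_positive_rate_is_low(self):
        # triplets with identical A and B rates should rarely clear the screen
        rng = np.random.default_rng(2024)
        passed = sum(
            separability_log_ibf(rng.poisson(10, 15), rng.poisson(10, 15)) > 3
            for _ in range(200)
        )
        assert passed / 200 < 0.1


class TestScreenTriplet:
    def _triplet(self, a, b, ab):
        return Triplet("u", "A|B", a, b, ab)

    def test_too_few_trials(self):
        t = self._triplet(RATE20[:4], RATE2, RATE2)
        report = screen_triplet(t)
        assert not report.included
        assert "trials" in report.failure_reasons

    def test_high_mean_fano(self):
        # fano_a = 4.5, fano_b = 2.0 -> mean 3.25 > 3
        a = [0, 0, 0, 9, 9, 0, 0, 9, 0, 0]   # mean 2.7, var 18.9 -> fano 4.68
        cfg = ScreeningConfig()
        t = self._triplet(a, RATE2, RATE2)
        report = screen_triplet(t, cfg)
        assert report.mean_fano == pytest.approx((report.fano_a + report.fano_b) / 2)
        if report.mean_fano > cfg.max_mean_fano:
            assert "fano" in report.failure_reasons

    def test_mean_fano_exactly_at_cap_is_retained(self):
        report = screen_triplet(self._triplet(RATE20, RATE2, RATE2),
                                ScreeningConfig(max_mean_fano=100.0))
        assert "fano" not in report.failure_reasons

    def test_well_behaved_triplet_included(self):
        (pair,) = simulate_population(
            [RegimeSpec(regime="mixture", lambda_a=20, lambda_b=5)],
            master_seed=3).pairs
        report = screen_triplet(pair[0])
        assert report.included
        assert report.failure_reasons == frozenset()

    def test_all_failures_recorded_not_just_first(self):
        t = self._triplet([5, 5, 5, 5], [5, 6, 5, 4], [5, 5, 5, 5])
        report = screen_triplet(t)
        assert {"trials", "separability"} <= report.failure_reasons

    def test_relabeling_symmetry(self):
        t = self._triplet(RATE20, RATE2, RATE2)
        fwd = screen_triplet(t)
        rev = screen_triplet(t.swapped())
        assert fwd.mean_fano == pytest.approx(rev.mean_fano)
        assert fwd.log_ibf_separation == pytest.approx(rev.log_ibf_separation)
        assert fwd.included == rev.included

    def test_stricter_fano_screen_is_subset(self):
        specs = [RegimeSpec(regime="mixture", dispersion=d, seed=i)
                 for i, d in enumerate([1.0] * 20 + [2.5] * 20 + [5.0] * 10)]
        triplets = simulate_population(specs, master_seed=17).triplets
        default_in = {r.triplet.unit_id for r in screen_triplets(triplets)
                      if r.included}
        strict_in = {r.triplet.unit_id
                     for r in screen_triplets(triplets, ScreeningConfig(max_mean_fano=2.0))
                     if r.included}
        assert strict_in <= default_in
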