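"""Category tallies, prevalence contrasts and histogram smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikemux.io import Triplet
from spikemux.model import TripletClassification
from spikemux.population import (CategoryTally, DegenerateTableError,
                                 compare_mixture_prevalence, kernel_smooth,
                                 mixture_proportion, smooth_count_histogram,
                                 tally_classifications)

from oracles import pearson_chi2


def _cls(winner, posterior):
    t = Triplet("u", "A|B", [1, 2], [1, 2], [1, 2])
    post = {h: (1 - posterior) / 3 for h in
            ("mixture", "intermediate", "single", "outside")}
    post[winner] = posterior
    return TripletClassification(
        triplet=t, log_marginal={}, posterior=post, winner=winner,
        winner_posterior=posterior, fluctuating=False,
        alpha_posterior_mean=0.5, single_branch="A")


def _tally(mixture, other, regime="r"):
    return CategoryTally(regime=regime,
                         counts={"mixture": mixture, "intermediate": other,
                                 "single": 0, "outside": 0})


class TestTally:
    def test_threshold_is_inclusive(self):
        cls = [_cls("mixture", 0.9), _cls("mixture", 0.7), _cls("single", 0.5)]
        tally = tally_classifications(cls, threshold=0.67)
        assert tally.counts["mixture"] == 2
        assert tally.n_unclassified == 1
        boundary = tally_classifications([_cls("mixture", 0.67)], threshold=0.67)
        assert boundary.counts["mixture"] == 1  # "0.67 or greater"

    def test_empty_input(self):
        tally = tally_classifications([])
        assert tally.n_classified == 0 and tally.n_unclassified == 0

    def test_zero_threshold_classifies_everything(self):
        cls = [_cls("mixture", 0.3), _cls("outside", 0.26)]
        tally = tally_classifications(cls, threshold=0.0)
        assert tally.n_unclassified == 0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(
        st.sampled_from(["mixture", "intermediate", "single", "outside"]),
        st.floats(0.26, 0.999)), max_size=40),
        st.floats(0.0, 0.95), st.floats(0.0, 0.95))
    def test_totals_and_threshold_monotonicity(self, spec, thr1, thr2):
        cls = [_cls(w, p) for w, p in spec]
        lo, hi = sorted([thr1, thr2])
        t_lo = tally_classifications(cls, threshold=lo)
        t_hi = tally_classifications(cls, threshold=hi)
        assert t_lo.total == t_hi.total == len(cls)
        for h in t_lo.counts:
            assert t_hi.counts[h] <= t_lo.counts[h]


class TestMixtureProportion:
    @pytest.mark.parametrize("counts,expected", [
        ({"mixture": 9, "intermediate": 11, "single": 0, "outside": 0}, 0.45),
        ({"mixture": 0, "intermediate": 5, "single": 5, "outside": 5}, 0.0),
        ({"mixture": 7, "intermediate": 0, "single": 0, "outside": 0}, 1.0),
    ])
    def test_arithmetic(self, counts, expected):
        assert mixture_proportion(CategoryTally("r", counts)) == pytest.approx(expected)

    def test_zero_classified_signalled(self):
        with pytest.raises(ValueError):
            mixture_proportion(_tally(0, 0))


class TestCompareMixturePrevalence:
    def test_identical_proportions(self):
        res = compare_mixture_prevalence(_tally(30, 70), _tally(30, 70))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_matches_textbook_formula(self):
        res = compare_mixture_prevalence(_tally(45, 55), _tally(2, 140))
        assert res.statistic == pytest.approx(
            pearson_chi2([[45, 55], [2, 140]]), rel=1e-12)

    def test_symmetry(self):
        r1 = compare_mixture_prevalence(_tally(45, 55), _tally(2, 140))
        r2 = compare_mixture_prevalence(_tally(2, 140), _tally(45, 55))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_table_signalled(self):
        with pytest.raises(DegenerateTableError):
            compare_mixture_prevalence(_tally(0, 10), _tally(0, 20))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_agrees_with_brute_force_on_random_tables(self, cells):
        a, b, c, d = cells
        res = compare_mixture_prevalence(_tally(a, b), _tally(c, d))
        assert res.statistic == pytest.approx(pearson_chi2([[a, b], [c, d]]),
                                              rel=1e-9)


class TestSmoothing:
    def test_kernel_arithmetic_with_edge_replication(self):
        np.testing.assert_allclose(kernel_smooth([0, 4, 0]), [1, 2, 1])

    def test_constant_histogram_unchanged(self):
        np.testing.assert_allclose(kernel_smooth([3.0] * 8), [3.0] * 8)

    def test_mass_preserved_for_interior_inputs(self):
        hist = np.array([0, 0, 5, 9, 7, 2, 0, 0], dtype=float)
        assert kernel_smooth(hist).sum() == pytest.approx(hist.sum())

    def test_spline_interpolates_through_kernel_stage(self):
        hist = [0, 4, 0, 6, 2]
        x, y = smooth_count_histogram(hist, upsample=10)
        stage = kernel_smooth(hist)
        np.testing.assert_allclose(y[::10], stage, atol=1e-12)
        assert x.size == (len(hist) - 1) * 10 + 1

    def test_short_input_warns_and_returns_unsmoothed(self):
        with pytest.warns(UserWarning):
            x, y = smooth_count_histogram([1.0, 2.0])
        np.testing.assert_allclose(y, [1.0, 2.0])
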