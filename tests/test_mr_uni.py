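"""Univariable two-sample MR estimators and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrglyc.mr_uni import (
    InsufficientInstrumentsError,
    chisq_upper_p,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)
from .conftest import make_hset


class TestWaldRatio:
    def test_hand_division(self):
        theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        theta, _ = wald_ratio(0.2, 0.01, 0.0, 0.05)
        assert theta == 0.0

    def test_orientation_invariance(self):
        t1, s1 = wald_ratio(0.1, 0.01, 0.05, 0.02)
        t2, s2 = wald_ratio(-0.1, 0.01, -0.05, 0.02)
        assert t1 == t2 and s1 == s2

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_two_ratio_hand_example(self):
        # ratios 0.5 and 0.3 with SEs 0.1, 0.2 -> weights (100, 25)
        hs = make_hset([1.0, 1.0], [1e-6, 1e-6], [0.5, 0.3], [0.1, 0.2])
        est, het = ivw(hs, mode="fixed")
        assert est.estimate == pytest.approx(0.46)
        assert est.se == pytest.approx(0.08944, abs=5e-6)
        assert het.Q == pytest.approx(0.8)
        assert het.df == 1

    def test_equal_ratios_have_zero_q_and_equal_ses(self):
        hs = make_hset([1.0] * 4, [1e-6] * 4, [0.2] * 4, [0.1, 0.2, 0.3, 0.4])
        fe, het = ivw(hs, mode="fixed")
        re_, _ = ivw(hs, mode="multiplicative_random")
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.I2 == 0.0
        assert fe.se == re_.se

    def test_single_instrument_rejected_but_matches_wald_limit(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hs)
        theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        hs2 = make_hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
        est, _ = ivw(hs2, mode="fixed")
        assert est.estimate == pytest.approx(theta)

    def test_fixed_effect_equals_weighted_regression_through_origin(self, rng):
        """IVW with ratio weights equals the WLS-through-origin slope of
        Gamma on gamma with weights sigma_Gamma^-2 (independent closed form)."""
        for _ in range(100):
            J = rng.integers(2, 11)
            gamma = rng.normal(0.1, 0.05, J)
            gamma[gamma == 0] = 0.01
            sG = rng.uniform(0.01, 0.1, J)
            Gamma = rng.normal(0.0, 0.2, J)
            hs = make_hset(gamma, np.full(J, 1e-6), Gamma, sG)
            est, _ = ivw(hs, mode="fixed")
            w = sG**-2
            slope = np.sum(w * gamma * Gamma) / np.sum(w * gamma**2)
            assert est.estimate == pytest.approx(slope, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        gamma = rng.normal(0.1, 0.03, 10)
        hs = make_hset(gamma, np.full(10, 1e-6), rng.normal(0, 0.1, 10),
                       rng.uniform(0.02, 0.08, 10))
        fe, _ = ivw(hs, "fixed")
        re_, _ = ivw(hs, "multiplicative_random")
        assert re_.se >= fe.se

    def test_or_per10_round_trip(self):
        hs = make_hset([1.0, 1.0], [1e-6] * 2, [0.01, 0.012], [0.002, 0.002])
        est, _ = ivw(hs)
        assert np.log(est.or_per10) / 10 == pytest.approx(est.estimate, abs=1e-12)
        assert est.ci_low <= est.estimate <= est.ci_high


class TestEgger:
    def test_exact_collinear_fit(self):
        hs = make_hset([0.1, 0.2, 0.3], [1e-6] * 3, [0.05, 0.10, 0.15],
                       [0.01, 0.02, 0.03])
        res = egger(hs)
        assert res.slope.estimate == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_moves_intercept_only(self, rng):
        gamma = rng.uniform(0.05, 0.3, 8)
        Gamma = 0.4 * gamma + rng.normal(0, 0.01, 8)
        sG = rng.uniform(0.01, 0.05, 8)
        base = egger(make_hset(gamma, np.full(8, 1e-6), Gamma, sG))
        shifted = egger(make_hset(gamma, np.full(8, 1e-6), Gamma + 0.02, sG))
        assert shifted.slope.estimate == pytest.approx(base.slope.estimate, abs=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + 0.02, abs=1e-10)

    def test_insufficient_instruments(self):
        hs = make_hset([0.1, 0.2], [1e-6] * 2, [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(hs)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        hs = make_hset([1.0] * 3, [1e-6] * 3, [0.2, 0.4, 0.6], [0.1] * 3)
        est = weighted_median(hs, n_boot=100, seed=1)
        assert est.estimate == pytest.approx(0.4)

    def test_hand_interpolation_with_unequal_weights(self):
        # normalized weights (0.25, 0.25, 0.5): cumulative midpoints
        # (0.125, 0.375, 0.75); interpolate theta at 0.5 -> 0.4 + 0.2/3
        sG = np.array([2.0, 2.0, np.sqrt(2.0)])
        hs = make_hset([1.0] * 3, [1e-6] * 3, [0.2, 0.4, 0.6], sG)
        est = weighted_median(hs, n_boot=100, seed=1)
        assert est.estimate == pytest.approx(0.4 + 0.2 / 3, abs=1e-10)

    def test_seeded_bootstrap_reproducible(self):
        hs = make_hset([1.0] * 5, [0.1] * 5, [0.1, 0.2, 0.3, 0.4, 0.5], [0.1] * 5)
        a = weighted_median(hs, seed=7)
        b = weighted_median(hs, seed=7)
        assert a.estimate == b.estimate and a.se == b.se


class TestChisqUpperP:
    @pytest.mark.parametrize("stat,df,expected", [
        (141.67, 121, 0.096),
        (142.30, 121, 0.090),
        (134.33, 121, 0.192),
    ])
    def test_reproduces_validity_p_values(self, stat, df, expected):
        assert chisq_upper_p(stat, df) == pytest.approx(expected, abs=5e-4)

    def test_zero_statistic(self):
        assert chisq_upper_p(0.0, 5) == 1.0


class TestEstimatorInvariances:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_sign_flip_invariance(self, seed):
        """All estimators are invariant to flipping (gamma_j, Gamma_j) jointly."""
        rng = np.random.default_rng(seed)
        J = 6
        gamma = rng.uniform(0.05, 0.3, J)
        Gamma = rng.normal(0, 0.1, J)
        sg, sG = np.full(J, 0.01), rng.uniform(0.02, 0.08, J)
        flip = np.where(rng.random(J) < 0.5, -1.0, 1.0)
        a = make_hset(gamma, sg, Gamma, sG)
        b = make_hset(gamma * flip, sg, Gamma * flip, sG)
        assert ivw(a)[0].estimate == pytest.approx(ivw(b)[0].estimate, rel=1e-10)
        assert egger(a).slope.estimate == pytest.approx(egger(b).slope.estimate, rel=1e-10)
        assert (weighted_median(a, n_boot=100, seed=0).estimate
                == pytest.approx(weighted_median(b, n_boot=100, seed=0).estimate, rel=1e-10))

    def test_exposure_rescaling_equivariance(self, rng):
        """Measuring the exposure in units c times larger divides every
        estimate by c (theta scale equivariance)."""
        c = 2.5
        gamma = rng.uniform(0.05, 0.3, 8)
        Gamma = rng.normal(0, 0.1, 8)
        sg, sG = np.full(8, 0.01), rng.uniform(0.02, 0.08, 8)
        a = make_hset(gamma, sg, Gamma, sG)
        b = make_hset(gamma * c, sg * c, Gamma, sG)
        assert ivw(b)[0].estimate == pytest.approx(ivw(a)[0].estimate / c, rel=1e-10)
        assert egger(b).slope.estimate == pytest.approx(egger(a).slope.estimate / c, rel=1e-10)
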