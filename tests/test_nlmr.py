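"""Non-linear MR: IV-free stratification, LACE, and curve fits."""

import numpy as np
import pytest

from mrglyc import nlmr, synth
from mrglyc.nlmr import (
    StratumEstimate,
    fracpoly_fit,
    iv_free_exposure,
    piecewise_fit,
    stratify_and_lace,
)


def make_strata(x_means, laces, ses=None, n=500):
    ses = ses if ses is not None else [0.01] * len(x_means)
    return [StratumEstimate(index=i + 1, x_mean=x, lace=l, se=s, n=n)
            for i, (x, l, s) in enumerate(zip(x_means, laces, ses))]


def simulate(seed=11, n=5000, shape="linear", **kw):
    cfg = synth.SimConfig(seed=seed, n_exposure_cohort=1, n_outcome_cohort=n,
                          outcome_shape=shape, **kw)
    arr = synth.simulate_cohort_arrays(cfg, "outcome")
    return cfg, arr


class TestIVFreeExposure:
    def test_zero_weights_rejected(self, rng):
        G = rng.binomial(2, 0.3, (100, 5))
        with pytest.raises(ValueError, match="zero variance"):
            iv_free_exposure(G, rng.normal(size=100), np.zeros(5))

    def test_exposure_linear_in_score_gives_zero_residuals(self, rng):
        G = rng.binomial(2, 0.3, (200, 4)).astype(float)
        w = np.array([1.0, 2.0, 0.5, 1.5])
        x = 3.0 + 2.0 * (G @ w)
        resid, score, beta_x = iv_free_exposure(G, x, w)
        assert np.allclose(resid, 0.0, atol=1e-9)
        assert beta_x == pytest.approx(2.0)

    def test_residuals_orthogonal_to_score(self):
        cfg, arr = simulate()
        resid, score, _ = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        assert abs(np.corrcoef(resid, score)[0, 1]) < 1e-10


class TestStratifyAndLace:
    def test_null_outcome_gives_null_lace_everywhere(self, rng):
        cfg, arr = simulate(seed=5, n=8000, theta=0.0)
        y = rng.binomial(1, 0.1, 8000).astype(float)  # independent of everything
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        strata = stratify_and_lace(arr["exposure"], score, y, resid, S=5, beta_x=bx)
        for s in strata:
            assert abs(s.lace) < 3 * s.se

    def test_strata_partition_and_order(self):
        cfg, arr = simulate(seed=6)
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        strata = stratify_and_lace(arr["exposure"], score, arr["event"], resid,
                                   S=10, beta_x=bx)
        assert sum(s.n for s in strata) == 5000
        x_means = [s.x_mean for s in strata]
        assert x_means == sorted(x_means)

    def test_location_shift_equivariance(self):
        """Shifting the exposure scale shifts stratum means but not LACE."""
        cfg, arr = simulate(seed=8)
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        a = stratify_and_lace(arr["exposure"], score, arr["event"], resid, S=5, beta_x=bx)
        resid2, score2, bx2 = iv_free_exposure(arr["genotypes"], arr["exposure"] + 50.0,
                                               cfg.beta_gx)
        b = stratify_and_lace(arr["exposure"] + 50.0, score2, arr["event"], resid2,
                              S=5, beta_x=bx2)
        for sa, sb in zip(a, b):
            assert sb.x_mean == pytest.approx(sa.x_mean + 50.0, abs=1e-8)
            assert sb.lace == pytest.approx(sa.lace, abs=1e-10)

    def test_single_class_stratum_excluded_with_warning(self, rng):
        cfg, arr = simulate(seed=9, n=3000)
        y = arr["event"].copy()
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        order = np.argsort(resid)
        y[order[:1000]] = 0.0  # empty the bottom stratum of events
        with pytest.warns(RuntimeWarning, match="single outcome class"):
            strata = stratify_and_lace(arr["exposure"], score, y, resid, S=3, beta_x=bx)
        assert len(strata) == 2


class TestFracPoly:
    def test_constant_lace_selects_linear_with_p_one(self):
        strata = make_strata([80, 90, 100, 110, 120], [0.01] * 5)
        fit = fracpoly_fit(strata)
        assert fit.power == 1.0
        assert fit.nonlinearity_p == 1.0
        # the curve is then the straight line theta * (x - ref)
        assert fit.curve(fit.reference + 10.0) == pytest.approx(0.1, abs=1e-9)

    def test_curve_anchored_at_reference(self):
        strata = make_strata([80, 90, 100, 110], [0.005, 0.01, 0.02, 0.04])
        fit = fracpoly_fit(strata)
        assert fit.curve(fit.reference) == pytest.approx(0.0, abs=1e-12)
        v, lo, hi = fit.curve_band(np.array([85.0, 105.0]))
        assert np.all(lo <= v) and np.all(v <= hi)

    def test_strong_curvature_detected(self):
        cfg, arr = simulate(seed=13, n=8000, shape="quadratic")
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        strata = stratify_and_lace(arr["exposure"], score, arr["event"], resid,
                                   S=10, beta_x=bx)
        fit = fracpoly_fit(strata)
        assert fit.nonlinearity_p < 0.05

    def test_quadratic_truth_gives_monotone_lace(self):
        cfg, arr = simulate(seed=14, n=20000, shape="quadratic")
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        strata = stratify_and_lace(arr["exposure"], score, arr["event"], resid,
                                   S=5, beta_x=bx)
        laces = np.array([s.lace for s in strata])
        rho = np.corrcoef(laces, [s.x_mean for s in strata])[0, 1]
        assert rho > 0.5

    def test_too_few_strata(self):
        with pytest.raises(ValueError, match="4 strata"):
            fracpoly_fit(make_strata([90, 100, 110], [0.01] * 3))

    def test_deterministic(self):
        strata = make_strata([80, 90, 100, 110], [0.005, 0.012, 0.019, 0.04],
                             ses=[0.008, 0.009, 0.01, 0.011])
        a, b = fracpoly_fit(strata), fracpoly_fit(strata)
        assert a.nonlinearity_p == b.nonlinearity_p and a.power == b.power


class TestPiecewise:
    def test_equal_slopes_reduce_to_straight_line(self):
        strata = make_strata([85, 95, 105, 115], [0.02] * 4)
        fit = piecewise_fit(strata, reference=95.0)
        xs = np.array([85.0, 100.0, 115.0])
        assert np.allclose(fit.curve(xs), 0.02 * (xs - 95.0))

    def test_curve_zero_at_reference(self):
        strata = make_strata([85, 95, 105], [0.01, 0.03, 0.02])
        fit = piecewise_fit(strata, reference=100.0)
        assert fit.curve(100.0) == pytest.approx(0.0)

    def test_hand_integration_two_strata(self):
        # slopes (0.01, 0.02), boundary 100, reference 90:
        # curve(110) = 0.01 * 10 + 0.02 * 10 = 0.3
        strata = make_strata([95, 105], [0.01, 0.02])
        fit = piecewise_fit(strata, reference=90.0, knots=[100.0], x_range=(80.0, 120.0))
        assert fit.curve(110.0) == pytest.approx(0.3)
        assert fit.curve(95.0) == pytest.approx(0.05)

    def test_continuity_at_knots(self):
        strata = make_strata([85, 95, 105, 115], [0.01, -0.02, 0.03, 0.005])
        fit = piecewise_fit(strata, reference=95.0)
        for k in fit.knots:
            below, above = fit.curve(k - 1e-9), fit.curve(k + 1e-9)
            assert above == pytest.approx(below, abs=1e-6)

    def test_reference_outside_range_rejected(self):
        strata = make_strata([95, 105], [0.01, 0.02])
        with pytest.raises(ValueError, match="outside"):
            piecewise_fit(strata, reference=50.0)

    def test_agrees_with_fracpoly_on_linear_truth(self):
        cfg, arr = simulate(seed=15, n=20000)
        resid, score, bx = iv_free_exposure(arr["genotypes"], arr["exposure"], cfg.beta_gx)
        strata = stratify_and_lace(arr["exposure"], score, arr["event"], resid,
                                   S=10, beta_x=bx)
        fp = fracpoly_fit(strata)
        pw = piecewise_fit(strata, reference=fp.reference)
        xs = np.linspace(strata[0].x_mean, strata[-1].x_mean, 21)
        v1, lo1, hi1 = fp.curve_band(xs)
        v2, lo2, hi2 = pw.curve_band(xs)
        # curves agree within the union of their 95% bands
        assert np.all(v2 <= hi1 + (hi2 - v2)) and np.all(v2 >= lo1 - (v2 - lo2))
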