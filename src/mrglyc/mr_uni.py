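"""Univariable two-sample Mendelian randomization estimators and diagnostics.

Given J harmonized instrument-exposure effects gamma_j (se sigma_gamma_j)
and instrument-outcome effects Gamma_j (se sigma_Gamma_j), each variant
supplies a Wald ratio theta_j = Gamma_j / gamma_j with first-order SE
sigma_Gamma_j / |gamma_j|.  The estimators combine these ratios under
different assumptions about invalid instruments:

* IVW — inverse-variance weighted mean of the ratios; unbiased when all
  instruments are valid.  Fixed-effect or multiplicative random-effects
  standard errors (random-effects, the default, inflates the SE by
  sqrt(Q/(J-1)) when Cochran's Q exceeds its degrees of freedom).
* MR-Egger — weighted regression of Gamma on gamma with a free
  intercept; the slope is the causal estimate under the InSIDE
  assumption and the intercept estimates the average directional
  pleiotropic effect.
* Weighted median — consistent when instruments carrying at least half
  of the weight are valid; SE by parametric bootstrap.

Estimates are on the per-unit (per mg/dL) log-odds scale; ``or_per10``
re-expresses them as an odds ratio per 10 units, the scale on which
glycaemic effects are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedSet

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "EggerResult",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "chisq_upper_p",
]

_Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the per-unit log-odds scale."""

    method: str
    estimate: float
    se: float
    pval: float
    per_unit: float = 10.0

    @property
    def ci_low(self) -> float:
        return self.estimate - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + _Z95 * self.se

    @property
    def or_per10(self) -> float:
        """Odds ratio per ``per_unit`` (default 10) units of exposure."""
        return float(np.exp(self.per_unit * self.estimate))

    @property
    def or_per10_ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.per_unit * self.ci_low)),
            float(np.exp(self.per_unit * self.ci_high)),
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test over the per-variant Wald ratios."""

    Q: float
    df: int
    pval: float

    @property
    def I2(self) -> float:
        if self.Q <= 0:
            return 0.0
        return max(0.0, (self.Q - self.df) / self.Q)


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _wald_two_sided(estimate: float, se: float) -> float:
    if se <= 0:
        return 1.0 if estimate == 0 else 0.0
    return float(2 * stats.norm.sf(abs(estimate) / se))


def chisq_upper_p(stat: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if stat < 0:
        raise ValueError("chi-square statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(stat, df))


def wald_ratio(gamma: float, sigma_gamma: float, Gamma: float, sigma_Gamma: float) -> tuple[float, float]:
    """Single-variant causal estimate Gamma/gamma with first-order delta SE.

    The first-order SE, sigma_Gamma/|gamma|, ignores uncertainty in gamma
    (the no-measurement-error approximation standard in two-sample MR).
    """
    if gamma == 0:
        raise ZeroDivisionError("undefined instrument: gamma = 0")
    return Gamma / gamma, sigma_Gamma / abs(gamma)


def _ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    gamma = hset.gamma
    if np.any(gamma == 0):
        raise ZeroDivisionError("undefined instrument: gamma = 0")
    theta = hset.Gamma_out / gamma
    se = hset.sigma_Gamma / np.abs(gamma)
    return theta, se


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_random") -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance weighted combination of the per-variant Wald ratios.

    ``mode="fixed"`` uses the fixed-effect SE (sum of weights)^-1/2;
    ``mode="multiplicative_random"`` (default) scales it by
    max(1, sqrt(Q/(J-1))), so heterogeneity beyond chance widens the CI
    but can never shrink it.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    J = len(hset)
    if J < 2:
        raise InsufficientInstrumentsError("IVW requires J >= 2 (use wald_ratio for J = 1)")
    theta, se = _ratios(hset)
    w = se**-2
    est = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - est) ** 2))
    df = J - 1
    het = HeterogeneityResult(Q=Q, df=df, pval=chisq_upper_p(Q, df))
    se_fixed = float(np.sum(w) ** -0.5)
    if mode == "fixed":
        se_out = se_fixed
    else:
        se_out = se_fixed * max(1.0, np.sqrt(Q / df))
    tag = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return MREstimate(method=tag, estimate=est, se=se_out, pval=_wald_two_sided(est, se_out)), het


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    Variants are first oriented so every gamma_j > 0 (flipping Gamma_j in
    step) — the intercept is orientation-dependent and this is the
    established convention.  Weights are sigma_Gamma^-2; standard errors
    use the multiplicative residual scale with a floor of 1.
    """
    J = len(hset)
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger requires J >= 3")
    gamma, Gamma = hset.gamma.copy(), hset.Gamma_out.copy()
    sG = hset.sigma_Gamma
    if np.any(gamma == 0):
        raise ZeroDivisionError("undefined instrument: gamma = 0")
    flip = np.sign(gamma)
    gamma, Gamma = gamma * flip, Gamma * flip
    if np.ptp(gamma) == 0:
        raise ValueError("collinearity: no variance in oriented gamma")

    X = sm.add_constant(gamma)
    fit = sm.WLS(Gamma, X, weights=sG**-2).fit()
    # multiplicative random-effects scale, floored at 1 (never narrower than fixed-effect)
    resid_scale = float(np.sqrt(fit.scale)) if fit.scale > 0 else 1.0
    se_fixed = np.asarray(fit.bse) / resid_scale if fit.scale > 0 else np.asarray(fit.bse)
    se_b0, se_b1 = se_fixed * max(1.0, resid_scale)
    b0, b1 = np.asarray(fit.params)
    slope = MREstimate(
        method="egger", estimate=float(b1), se=float(se_b1),
        pval=_wald_two_sided(b1, se_b1),
    )
    return EggerResult(
        slope=slope,
        intercept=float(b0), intercept_se=float(se_b0),
        intercept_pval=_wald_two_sided(b0, se_b0),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    w = w / np.sum(w)
    S = np.cumsum(w)
    p = S - w / 2  # cumulative midpoints
    return float(np.interp(0.5, p, theta))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the Wald ratios, SE by parametric bootstrap.

    The estimate interpolates the sorted ratios at cumulative weight 0.5;
    it is consistent as long as valid instruments carry a majority of the
    weight.  The bootstrap redraws (gamma_j, Gamma_j) from normal
    distributions centred on the observed estimates with their reported
    SEs, recomputes the weighted median, and takes the standard deviation.
    """
    J = len(hset)
    if J < 3:
        raise InsufficientInstrumentsError("weighted median requires J >= 3")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    theta, se = _ratios(hset)
    est = _weighted_median(theta, se**-2)

    rng = np.random.default_rng(seed)
    gamma, sg = hset.gamma, hset.sigma_gamma
    Gamma, sG = hset.Gamma_out, hset.sigma_Gamma
    boots = np.empty(n_boot)
    for b in range(n_boot):
        g = rng.normal(gamma, sg)
        G = rng.normal(Gamma, sG)
        ok = g != 0
        th = G[ok] / g[ok]
        boots[b] = _weighted_median(th, (sG[ok] / np.abs(g[ok])) ** -2)
    se_boot = float(np.std(boots, ddof=1))
    return MREstimate(method="weighted_median", estimate=est, se=se_boot,
                      pval=_wald_two_sided(est, se_boot))
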