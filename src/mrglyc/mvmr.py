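"""Multivariable Mendelian randomization on summary statistics.

MVMR regresses the instrument-outcome effects on the instrument effects
for K exposures jointly (weighted least squares, no intercept), so each
coefficient is the *direct* effect of that exposure on the outcome,
conditional on the others.  Two diagnostics accompany the fit:

* a validity Q statistic — the weighted residual sum of squares on
  J - K degrees of freedom; excess heterogeneity signals pleiotropy not
  captured by the included exposures;
* per-exposure conditional F statistics — how strongly the instruments
  predict one exposure beyond what the other exposures' effects explain.
  The conventional weak-instrument rule of thumb is F < 10.

Covariances between exposure effect estimates are taken as zero, as is
standard when each exposure's GWAS comes from a separate (or summary
only) source.  The conditional-F denominator convention (J - K + 1) is
a declared choice, recorded in the result metadata, because published
implementations differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mr_uni import HeterogeneityResult, MREstimate, _wald_two_sided, chisq_upper_p

__all__ = ["MVMRSet", "MVMRResult", "CollinearityError", "mvmr_fit", "conditional_f"]

CONDITIONAL_F_DENOMINATOR = "J - K + 1"


class CollinearityError(ValueError):
    pass


@dataclass
class MVMRSet:
    """Instrument effects on K exposures and one outcome, for J instruments."""

    gamma_mat: np.ndarray       # J x K instrument-exposure effects
    sigma_mat: np.ndarray       # J x K standard errors
    Gamma_out: np.ndarray       # length-J instrument-outcome effects
    sigma_Gamma: np.ndarray     # length-J standard errors
    exposure_names: Sequence[str]

    def __post_init__(self) -> None:
        self.gamma_mat = np.atleast_2d(np.asarray(self.gamma_mat, dtype=float))
        self.sigma_mat = np.atleast_2d(np.asarray(self.sigma_mat, dtype=float))
        self.Gamma_out = np.asarray(self.Gamma_out, dtype=float)
        self.sigma_Gamma = np.asarray(self.sigma_Gamma, dtype=float)
        J, K = self.gamma_mat.shape
        if self.sigma_mat.shape != (J, K):
            raise ValueError("sigma_mat shape does not match gamma_mat")
        if self.Gamma_out.shape != (J,) or self.sigma_Gamma.shape != (J,):
            raise ValueError("outcome vectors must have length J")
        if len(self.exposure_names) != K:
            raise ValueError("exposure_names length does not match K")
        if not J > K:
            raise ValueError("MVMR requires more instruments than exposures (J > K)")
        if np.any(self.sigma_mat <= 0) or np.any(self.sigma_Gamma <= 0):
            raise ValueError("all SEs must be positive")

    @property
    def J(self) -> int:
        return self.gamma_mat.shape[0]

    @property
    def K(self) -> int:
        return self.gamma_mat.shape[1]


@dataclass
class MVMRResult:
    direct_effects: list[MREstimate]
    q_validity: HeterogeneityResult
    conditional_F: list[float]
    exposure_names: list[str]
    metadata: dict = field(default_factory=dict)


def _check_rank(G: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(G) < G.shape[1]:
        raise CollinearityError(
            "gamma_mat is rank deficient; exposures "
            + ", ".join(names) + " do not have linearly independent instrument effects"
        )


def mvmr_fit(mset: MVMRSet) -> MVMRResult:
    """Weighted no-intercept regression of Gamma_out on the exposure-effect columns.

    Weights are sigma_Gamma^-2.  Coefficient SEs come from the weighted
    information matrix (fixed-effect); the validity Q is the weighted
    residual sum of squares with df = J - K and an upper-tail chi-square
    p-value.
    """
    G, Gamma, sG = mset.gamma_mat, mset.Gamma_out, mset.sigma_Gamma
    J, K = mset.J, mset.K
    _check_rank(G, mset.exposure_names)

    w = sG**-2
    Xw = G * w[:, None]
    info = G.T @ Xw                       # X' W X
    cov = np.linalg.inv(info)
    beta = cov @ (G.T @ (w * Gamma))
    resid = Gamma - G @ beta
    Q = float(np.sum(w * resid**2))
    df = J - K
    q_validity = HeterogeneityResult(Q=Q, df=df, pval=chisq_upper_p(Q, df))

    se = np.sqrt(np.diag(cov))
    effects = [
        MREstimate(method="mvmr_ivw", estimate=float(b), se=float(s),
                   pval=_wald_two_sided(float(b), float(s)))
        for b, s in zip(beta, se)
    ]
    cond_F = [conditional_f(mset, k) for k in range(K)]
    return MVMRResult(
        direct_effects=effects,
        q_validity=q_validity,
        conditional_F=cond_F,
        exposure_names=list(mset.exposure_names),
        metadata={"conditional_f_denominator": CONDITIONAL_F_DENOMINATOR},
    )


def conditional_f(mset: MVMRSet, exposure_index: int) -> float:
    """Conditional instrument-strength F statistic for one exposure.

    Regresses exposure k's instrument effects on the other exposures'
    effects with weights sigma_k^-2; the weighted residual sum of squares
    Q_xk, divided by J - K + 1, measures instrument strength specific to
    exposure k.  For K = 1 this reduces to the mean univariable F,
    sum_j (gamma_j / sigma_j)^2 / J.
    """
    G, S = mset.gamma_mat, mset.sigma_mat
    J, K = mset.J, mset.K
    if not 0 <= exposure_index < K:
        raise IndexError("exposure_index out of range")
    g_k = G[:, exposure_index]
    w = S[:, exposure_index] ** -2.0
    if K == 1:
        return float(np.sum(w * g_k**2) / J)
    others = np.delete(G, exposure_index, axis=1)
    _check_rank(others, [n for i, n in enumerate(mset.exposure_names) if i != exposure_index])
    Xw = others * w[:, None]
    coef = np.linalg.solve(others.T @ Xw, Xw.T @ g_k)
    resid = g_k - others @ coef
    Q_xk = float(np.sum(w * resid**2))
    return Q_xk / (J - K + 1)
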