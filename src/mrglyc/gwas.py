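"""Per-variant QC and association scans.

Mirrors the summary-statistic production step of a biobank GWAS at desk
scale (tens to thousands of variants, not millions): Hardy-Weinberg and
minor-allele-frequency filters, then one regression per variant of the
trait on allele dosage plus covariates.  Continuous traits use ordinary
least squares; binary traits use logistic maximum likelihood.  Effects
are per effect allele, with Wald standard errors and two-sided p-values.

QC conventions: MAF threshold is inclusive (a variant at exactly 0.01
passes) and HWE exclusion is strict (excluded only when p < threshold).
The HWE test is the 1-df chi-square goodness of fit, chosen over the
exact test for determinism and speed at this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import AssociationRecord, Variant

__all__ = [
    "QCReport",
    "ScanResult",
    "hwe_test",
    "qc_filter",
    "association_scan",
    "MAF_MIN_DEFAULT",
    "HWE_MIN_P_DEFAULT",
]

MAF_MIN_DEFAULT = 0.01
HWE_MIN_P_DEFAULT = 1e-6


@dataclass
class QCReport:
    """Outcome of per-variant QC: a partition of the input variants."""

    n_input: int
    n_pass: int
    failures: list[tuple[str, str, float]]  # (variant id, rule, offending statistic)
    passed: list[int]  # column indices retained, in input order

    def __post_init__(self) -> None:
        if self.n_pass + len(self.failures) != self.n_input:
            raise ValueError("QC report does not partition the input")


@dataclass
class ScanResult:
    """Per-variant association records plus variants flagged out of the scan."""

    records: list[AssociationRecord]
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    Compares observed genotype counts with the counts expected under the
    sample allele frequency.  Returns 1.0 when the observed counts match
    expectation exactly, and 1.0 by convention for a monomorphic variant
    (no 1-df departure is defined when one allele is absent).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    genotypes: np.ndarray,
    maf_min: float = MAF_MIN_DEFAULT,
    hwe_min_p: float = HWE_MIN_P_DEFAULT,
    variant_ids: Sequence[str] | None = None,
) -> QCReport:
    """Filter a dosage matrix (subjects x variants) on sample MAF and HWE.

    A variant passes when its sample MAF >= ``maf_min`` (inclusive) and its
    HWE p-value >= ``hwe_min_p``.  Each failure is reported with the rule it
    broke and the offending statistic.
    """
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise ValueError("genotypes must be a 2-D subjects x variants matrix")
    n, J = G.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(J)]
    if len(variant_ids) != J:
        raise ValueError("variant_ids length does not match matrix")

    failures: list[tuple[str, str, float]] = []
    passed: list[int] = []
    for j in range(J):
        g = G[:, j]
        freq = float(np.mean(g)) / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            failures.append((variant_ids[j], "maf", maf))
            continue
        counts = np.bincount(g.astype(int), minlength=3)
        p_hwe = hwe_test(int(counts[2]), int(counts[1]), int(counts[0]))
        if p_hwe < hwe_min_p:
            failures.append((variant_ids[j], "hwe", p_hwe))
            continue
        passed.append(j)
    return QCReport(n_input=J, n_pass=len(passed), failures=failures, passed=passed)


def _wald_p(beta: float, se: float) -> float:
    if se == 0:
        return 1e-300
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def association_scan(
    dosages: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    variants: Sequence[Variant] | None = None,
) -> ScanResult:
    """Per-variant regression of the trait on allele dosage plus covariates.

    family="linear": OLS of a continuous trait; family="logistic": Newton
    maximum-likelihood logistic regression of a 0/1 trait.  Standard errors
    come from the information matrix; p-values are two-sided Wald.  Variants
    whose fit is degenerate (perfect linear fit with zero residual SE,
    logistic separation or non-convergence) are flagged and excluded from
    the records rather than reported with a meaningless SE.
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    if G.ndim != 2:
        raise ValueError("dosages must be subjects x variants")
    n, J = G.shape
    if y.shape[0] != n:
        raise ValueError("trait length does not match dosage matrix")
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    if family == "logistic":
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
            raise ValueError("logistic scan requires a 0/1 trait with both classes present")

    if covariates is None:
        X_cov = np.empty((n, 0))
    else:
        X_cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X_cov.shape[0] != n:
            X_cov = X_cov.T
    if variants is None:
        variants = [
            Variant(id=f"v{j}", chrom="1", pos=j + 1, effect_allele="A", other_allele="G")
            for j in range(J)
        ]

    result = ScanResult(records=[])
    for j in range(J):
        X = np.column_stack([np.ones(n), G[:, j], X_cov])
        vid = variants[j].id
        if family == "linear":
            fit = sm.OLS(y, X).fit()
            beta, se = float(fit.params[1]), float(fit.bse[1])
            if se <= 1e-10 * max(1.0, abs(beta)) or not np.isfinite(se):
                result.flagged.append((vid, "degenerate-fit"))
                continue
            pval = _wald_p(beta, se)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.Logit(y, X).fit(disp=False, maxiter=50, tol=1e-8)
                except Exception:
                    result.flagged.append((vid, "non-converged"))
                    continue
            if not fit.mle_retvals.get("converged", False) or not np.all(np.isfinite(fit.bse)):
                result.flagged.append((vid, "non-converged"))
                continue
            beta, se = float(fit.params[1]), float(fit.bse[1])
            if se > 1e3:  # separation manifests as an exploding SE
                result.flagged.append((vid, "separation"))
                continue
            pval = _wald_p(beta, se)
        result.records.append(
            AssociationRecord(variant=variants[j], beta=beta, se=se,
                              pval=max(pval, 1e-300), n=n)
        )
    return result
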