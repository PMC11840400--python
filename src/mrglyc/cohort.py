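"""Observational stage: ICD-10 endpoint classification and Cox models.

Endpoints follow the registry definitions of an atherosclerotic
cardiovascular disease (ASCVD) composite: ischemic heart disease (IHD,
I20-I25, with acute myocardial infarction I21-I22 as a subtype), stroke
(I60-I69, split into hemorrhagic I60-I62 and thrombotic I63/I65-I66,
with the remaining I64/I67-I69 counting only toward total stroke), and
other CVD (I10-I15, I44-I49, I50, I51, I70-I74, R96).  The stroke
subtype boundaries are a recorded convention of this package — registry
papers rarely print their exact subcode lists.

The Cox stage fits a proportional-hazards model of the event endpoint
on fasting serum glucose plus a covariate set, with Efron tie handling,
and reports the hazard ratio per 10 mg/dL alongside a proportionality
check (score test on the scaled Schoenfeld residual trend).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .synth import SubjectRecord, cohort_arrays

__all__ = [
    "Endpoint",
    "CoxResult",
    "ClassificationError",
    "classify_icd10",
    "cox_fit",
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
]

_Z95 = float(stats.norm.ppf(0.975))

MODEL1_COVARIATES = ("age", "sex", "hdl", "ldl", "sbp", "alcohol", "smoking")
MODEL2_COVARIATES = MODEL1_COVARIATES + ("bmi", "exercise", "tg", "income")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")

CATEGORIES = ("ASCVD", "IHD", "AMI", "stroke_total", "stroke_thrombotic",
              "stroke_hemorrhagic", "other_cvd", "none")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class Endpoint:
    """Most specific endpoint category for one ICD-10 code.

    ``memberships`` expands the hierarchy: AMI is also IHD and ASCVD;
    stroke subtypes are also total stroke and ASCVD; other CVD is ASCVD.
    """

    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown endpoint category {self.category!r}")

    @property
    def memberships(self) -> frozenset[str]:
        chain = {
            "none": (),
            "ASCVD": ("ASCVD",),
            "other_cvd": ("other_cvd", "ASCVD"),
            "IHD": ("IHD", "ASCVD"),
            "AMI": ("AMI", "IHD", "ASCVD"),
            "stroke_total": ("stroke_total", "ASCVD"),
            "stroke_thrombotic": ("stroke_thrombotic", "stroke_total", "ASCVD"),
            "stroke_hemorrhagic": ("stroke_hemorrhagic", "stroke_total", "ASCVD"),
        }
        return frozenset(chain[self.category])


@dataclass(frozen=True)
class CoxResult:
    """Per-unit Cox coefficient with its per-10 mg/dL hazard-ratio view."""

    log_hr: float               # per mg/dL
    se: float
    pval: float
    n_events: int
    ph_check_p: float           # proportional-hazards score-test p for FSG
    model: str
    endpoint: str

    @property
    def hr_per10(self) -> float:
        return float(np.exp(10.0 * self.log_hr))

    @property
    def hr_per10_ci(self) -> tuple[float, float]:
        lo = np.exp(10.0 * (self.log_hr - _Z95 * self.se))
        hi = np.exp(10.0 * (self.log_hr + _Z95 * self.se))
        return float(lo), float(hi)


def _in_range(stem: str, lo: str, hi: str) -> bool:
    return lo <= stem <= hi


def classify_icd10(code: str) -> Endpoint:
    """Map an ICD-10 code to its most specific cardiovascular endpoint.

    Empty string means no event.  Codes that do not match ICD-10 syntax
    raise :class:`ClassificationError` naming the code.
    """
    if code == "":
        return Endpoint("none")
    cleaned = code.strip().upper()
    if not _ICD10_RE.match(cleaned):
        raise ClassificationError(f"malformed ICD-10 code: {code!r}")
    stem = cleaned[:3]

    if _in_range(stem, "I21", "I22"):
        return Endpoint("AMI")
    if _in_range(stem, "I20", "I25"):
        return Endpoint("IHD")
    if _in_range(stem, "I60", "I62"):
        return Endpoint("stroke_hemorrhagic")
    if stem == "I63" or _in_range(stem, "I65", "I66"):
        return Endpoint("stroke_thrombotic")
    if _in_range(stem, "I60", "I69"):
        return Endpoint("stroke_total")
    if (_in_range(stem, "I10", "I15") or _in_range(stem, "I44", "I49")
            or stem in ("I50", "I51") or _in_range(stem, "I70", "I74")
            or stem == "R96"):
        return Endpoint("other_cvd")
    return Endpoint("none")


def cox_fit(
    cohort: Sequence[SubjectRecord] | dict[str, np.ndarray],
    covariate_set: str = "model1",
    endpoint: str = "ASCVD",
) -> CoxResult:
    """Cox proportional-hazards fit of an endpoint on FSG plus covariates.

    ``covariate_set`` "model1" adjusts for age, sex, HDL, LDL, SBP,
    alcohol and smoking; "model2" additionally for BMI, exercise, TG and
    income.  The event indicator is membership of ``endpoint`` in the
    subject's classified ICD-10 code; subjects whose code maps elsewhere
    are censored at their follow-up time.  Ties are handled by Efron's
    method (lifelines' default).  ``hr_per10`` rescales the per-mg/dL
    coefficient to the conventional per-10 mg/dL hazard ratio.
    """
    if covariate_set not in ("none", "model1", "model2"):
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    covs = {"none": (), "model1": MODEL1_COVARIATES,
            "model2": MODEL2_COVARIATES}[covariate_set]
    arr = cohort if isinstance(cohort, dict) else cohort_arrays(cohort)

    events = np.array([
        endpoint in classify_icd10(str(c)).memberships for c in arr["event_code"]
    ], dtype=float)
    n_events = int(events.sum())
    if n_events < 2:
        raise ValueError(f"endpoint {endpoint}: fewer than 2 events")

    df = pd.DataFrame({"fsg": arr["exposure"], "time": arr["time"], "event": events})
    for c in covs:
        if c not in arr:
            raise KeyError(f"covariate {c!r} missing from cohort")
        df[c] = arr[c]

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood / separation
        raise RuntimeError(
            f"Cox fit diverged for endpoint {endpoint} ({covariate_set}): {exc}"
        ) from exc
    log_hr = float(cph.params_["fsg"])
    se = float(cph.standard_errors_["fsg"])

    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_p = float(ph.summary.loc["fsg", "p"]) if "fsg" in ph.summary.index else float("nan")

    return CoxResult(
        log_hr=log_hr, se=se,
        pval=float(2 * stats.norm.sf(abs(log_hr) / se)) if se > 0 else 0.0,
        n_events=n_events, ph_check_p=ph_p,
        model=covariate_set, endpoint=endpoint,
    )
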