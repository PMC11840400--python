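"""Synthetic two-cohort generator for the glucose-ASCVD analyses.

Emulates the data structure of a two-sample MR study of fasting serum
glucose (FSG) and atherosclerotic cardiovascular disease: a genomic
exposure cohort in which the instrument-exposure effects are estimated
(mean FSG 93.72 mg/dL) and a disjoint biobank-style outcome cohort
supplying instrument-outcome effects, follow-up times and ICD-10 event
codes.  Defaults follow the study conditions: J = 42
independent glucose-raising variants explaining ~3% of exposure
variance, a causal effect of 0.01 log-odds per mg/dL (odds ratio ~1.11
per 10 mg/dL), and correlated secondary exposures (SBP, LDL) whose
instrument strength mirrors the weak-SBP / strong-LDL pattern of the
multivariable model.

Structural model, per subject i with dosages g_ij ~ Binomial(2, maf_j):

    x_i  = mu_x + sum_j beta_j g_ij + c_x U_i + e_i          (FSG, mg/dL)
    eta_i = f(x_i) + sum_j alpha_j g_ij + theta_S SBP_i*
            + theta_L LDL_i* + c_y U_i + covariate terms
    T_i  ~ Exponential(rate = lambda_0 exp(eta_i)),  censored at t_max

with U a standard-normal latent confounder shared by exposure, SBP,
LDL, and outcome, and f linear, quadratic, or threshold in x.  The
binary event indicator (event before administrative censoring) and the
survival time share the same linear predictor, so the Cox and logistic
stages estimate the same underlying effect.  alpha_j are direct
(pleiotropic) variant-outcome effects: zero, balanced (mean 0) or
directional (non-zero mean).

All randomness flows from one integer seed through named sub-streams,
so any stage can be regenerated independently and reruns are
byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import gwas
from .summary_io import AssociationRecord, Variant

__all__ = [
    "SecondaryExposure",
    "SimConfig",
    "SubjectRecord",
    "simulate_two_cohorts",
    "simulate_cohort_arrays",
    "cohort_arrays",
    "cohort_to_summary_stats",
]

# non-palindromic allele pairs only, so harmonization keeps every variant
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))

# ICD-10 codes assigned to simulated events, with weights roughly matching
# the endpoint mix of a cardiovascular registry (IHD ~ half, of which a
# minority AMI; stroke over a third; remainder other CVD).
_EVENT_CODES = ("I20", "I21", "I22", "I25", "I63", "I65", "I64",
                "I60", "I61", "I10", "I50", "I70", "R96")
_EVENT_WEIGHTS = (0.28, 0.08, 0.03, 0.15, 0.14, 0.04, 0.07,
                  0.05, 0.03, 0.05, 0.04, 0.03, 0.01)


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SecondaryExposure:
    """A correlated exposure (SBP, LDL) sharing the instrument panel.

    ``h2`` is the fraction of the exposure's variance explained by the
    panel; per-variant effects are drawn mean-zero (balanced), so they
    perturb univariable MR as balanced pleiotropy while giving MVMR a
    genuine second exposure.  ``theta`` is the causal effect on the
    outcome log-odds per unit.
    """

    mean: float
    sd: float
    h2: float
    theta: float
    confounder_effect: float
    beta_g: np.ndarray | None = None


def _default_secondaries() -> dict[str, SecondaryExposure]:
    return {
        # SBP: weak instrument strength (conditional F below the ~10 rule of
        # thumb at n = 20k), LDL: strong — mirroring the weak-SBP pattern the
        # multivariable model is meant to diagnose.
        "sbp": SecondaryExposure(mean=121.0, sd=15.0, h2=0.015, theta=0.02,
                                 confounder_effect=5.0),
        "ldl": SecondaryExposure(mean=112.0, sd=31.0, h2=0.08, theta=0.005,
                                 confounder_effect=8.0),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic two-cohort study.

    Vector fields left as ``None`` are derived deterministically from the
    seed: mafs ~ U(0.05, 0.45); equal glucose-raising effects ``beta_gx``
    scaled so the panel explains ``h2_exposure`` of the exposure variance;
    pleiotropic effects ``alpha`` drawn per ``pleiotropy_mode``.
    """

    seed: int = 0
    J: int = 42
    maf: np.ndarray | None = None
    n_exposure_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    beta_gx: np.ndarray | None = None
    h2_exposure: float = 0.03
    theta: float = 0.01                      # log-odds per mg/dL
    alpha: np.ndarray | None = None
    pleiotropy_mode: str = "none"            # none | balanced | directional
    pleiotropy_mean: float = 0.02
    pleiotropy_sd: float = 0.01
    exposure_mean: float = 93.72             # mg/dL
    exposure_sd: float = 18.0                # mg/dL, total
    confounder_effects: tuple[float, float] = (5.0, -0.25)
    secondary_exposures: dict[str, SecondaryExposure] = field(default_factory=_default_secondaries)
    outcome_shape: str = "linear"            # linear | quadratic | threshold
    quadratic_coeff: float = 1.5e-3          # log-odds per (mg/dL)^2, quadratic shape
    threshold_value: float = 110.0           # mg/dL, threshold shape
    baseline_hazard: float = 0.006           # events per person-year
    followup_years: float = 13.0

    def __post_init__(self) -> None:
        if self.J < 1 or self.n_exposure_cohort < 1 or self.n_outcome_cohort < 1:
            raise ValueError("J and cohort sizes must be >= 1")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_shape not in ("linear", "quadratic", "threshold"):
            raise ValueError(f"unknown outcome_shape {self.outcome_shape!r}")
        if self.maf is None:
            self.maf = _stream(self.seed, "maf").uniform(0.05, 0.45, self.J)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.J,):
            raise ValueError("maf vector length must equal J")
        if np.any(self.maf < 0.005) or np.any(self.maf > 0.5):
            raise ValueError("mafs must lie in [0.005, 0.5]")
        het = 2.0 * self.maf * (1.0 - self.maf)
        if self.beta_gx is None:
            b = np.sqrt(self.h2_exposure * self.exposure_sd**2 / np.sum(het))
            self.beta_gx = np.full(self.J, b)
        self.beta_gx = np.asarray(self.beta_gx, dtype=float)
        if self.beta_gx.shape != (self.J,):
            raise ValueError("beta_gx length must equal J")
        if self.alpha is None:
            if self.pleiotropy_mode == "none":
                self.alpha = np.zeros(self.J)
            else:
                mean = self.pleiotropy_mean if self.pleiotropy_mode == "directional" else 0.0
                self.alpha = _stream(self.seed, "alpha").normal(mean, self.pleiotropy_sd, self.J)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.J,):
            raise ValueError("alpha length must equal J")
        for name, sec in self.secondary_exposures.items():
            if sec.beta_g is None:
                raw = _stream(self.seed, f"beta_{name}").normal(0.0, 1.0, self.J)
                scale = np.sqrt(sec.h2 * sec.sd**2 / np.sum(het * raw**2))
                sec.beta_g = raw * scale
            sec.beta_g = np.asarray(sec.beta_g, dtype=float)
            if sec.beta_g.shape != (self.J,):
                raise ValueError(f"secondary exposure {name}: beta_g length must equal J")
        # residual exposure noise after genetics and confounding
        resid_var = (self.exposure_sd**2
                     - np.sum(het * self.beta_gx**2)
                     - self.confounder_effects[0] ** 2)
        if resid_var <= 0:
            raise ValueError("genetic + confounder variance exceeds exposure_sd^2")
        self._resid_sd = float(np.sqrt(resid_var))

    def variants(self) -> list[Variant]:
        """Variant metadata (ids, alleles, frequencies) for the panel."""
        rng = _stream(self.seed, "alleles")
        pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), self.J)]
        return [
            Variant(id=f"rs{j + 1}", chrom=str(j % 22 + 1), pos=10_000 + 137 * j,
                    effect_allele=ea, other_allele=oa, eaf=float(self.maf[j]))
            for j, (ea, oa) in enumerate(pairs)
        ]


@dataclass
class SubjectRecord:
    """One simulated cohort member."""

    genotypes: np.ndarray           # dosages in {0,1,2}, length J
    exposure: float                 # FSG, mg/dL
    covariates: dict[str, float]    # age, sex, sbp, ldl, hdl, smoking, alcohol, ...
    event_code: str                 # ICD-10 code, or "" for no event
    time: float                     # follow-up years

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("follow-up time must be positive")

    @property
    def event(self) -> bool:
        return self.event_code != ""


def _curve(x: np.ndarray, config: SimConfig) -> np.ndarray:
    """Exposure-outcome relation f(x) on the log-odds scale, centred at mu_x."""
    d = x - config.exposure_mean
    if config.outcome_shape == "linear":
        return config.theta * d
    if config.outcome_shape == "quadratic":
        return config.theta * d + config.quadratic_coeff * d**2
    return config.theta * np.maximum(0.0, x - config.threshold_value)


def simulate_cohort_arrays(config: SimConfig, which: str) -> dict[str, np.ndarray]:
    """Simulate one cohort as flat arrays (the fast path used internally).

    ``which`` ("exposure" or "outcome") selects the cohort size and the
    random sub-streams, making the two cohorts disjoint and independent
    as a two-sample design requires.
    """
    if which not in ("exposure", "outcome"):
        raise ValueError("which must be 'exposure' or 'outcome'")
    n = config.n_exposure_cohort if which == "exposure" else config.n_outcome_cohort
    rng = _stream(config.seed, f"cohort-{which}")

    G = rng.binomial(2, config.maf[None, :], size=(n, config.J)).astype(np.int8)
    U = rng.normal(0.0, 1.0, n)
    c_x, c_y = config.confounder_effects

    genetic = G @ config.beta_gx
    x = (config.exposure_mean + genetic - float(np.sum(config.beta_gx * 2 * config.maf))
         + c_x * U + rng.normal(0.0, config._resid_sd, n))

    age = rng.normal(52.0, 9.0, n)
    sex = rng.binomial(1, 0.40, n).astype(float)          # 1 = female
    smoking = rng.binomial(1, 0.50, n).astype(float)
    alcohol = rng.binomial(1, 0.80, n).astype(float)
    exercise = rng.binomial(1, 0.40, n).astype(float)
    hdl = 53.0 - 2.0 * U + rng.normal(0.0, 11.0, n)
    bmi = 23.4 + 1.5 * U + rng.normal(0.0, 2.8, n)
    tg = 130.0 + 25.0 * U + rng.normal(0.0, 80.0, n)
    income = 430.0 - 25.0 * U + rng.normal(0.0, 200.0, n)

    secondaries: dict[str, np.ndarray] = {}
    eta = _curve(x, config) + G @ config.alpha + c_y * U
    for name, sec in config.secondary_exposures.items():
        resid_sd = np.sqrt(max(
            sec.sd**2
            - np.sum(2 * config.maf * (1 - config.maf) * sec.beta_g**2)
            - sec.confounder_effect**2,
            1e-6,
        ))
        val = (sec.mean + G @ sec.beta_g
               - float(np.sum(sec.beta_g * 2 * config.maf))
               + sec.confounder_effect * U + rng.normal(0.0, resid_sd, n))
        secondaries[name] = val
        eta = eta + sec.theta * (val - sec.mean)
    eta = eta + 0.04 * (age - 52.0) - 0.4 * sex + 0.3 * smoking

    rate = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= config.followup_years
    time = np.minimum(t_event, config.followup_years)
    if not np.any(event):
        codes = np.full(n, "", dtype=object)
    else:
        draws = rng.choice(_EVENT_CODES, size=int(event.sum()), p=_EVENT_WEIGHTS)
        codes = np.full(n, "", dtype=object)
        codes[event] = draws

    return {
        "genotypes": G,
        "exposure": x,
        "age": age, "sex": sex, "smoking": smoking, "alcohol": alcohol,
        "exercise": exercise, "hdl": hdl, "bmi": bmi, "tg": tg, "income": income,
        **secondaries,
        "event": event.astype(float),
        "event_code": codes,
        "time": time,
    }


_COVARIATE_KEYS = ("age", "sex", "sbp", "ldl", "hdl", "smoking", "alcohol",
                   "exercise", "bmi", "tg", "income")


def _arrays_to_records(arr: dict[str, np.ndarray]) -> list[SubjectRecord]:
    n = arr["exposure"].shape[0]
    cov_keys = [k for k in _COVARIATE_KEYS if k in arr]
    return [
        SubjectRecord(
            genotypes=arr["genotypes"][i],
            exposure=float(arr["exposure"][i]),
            covariates={k: float(arr[k][i]) for k in cov_keys},
            event_code=str(arr["event_code"][i]),
            time=float(arr["time"][i]),
        )
        for i in range(n)
    ]


def cohort_arrays(cohort: Sequence[SubjectRecord]) -> dict[str, np.ndarray]:
    """Flatten a list of subject records back into analysis arrays."""
    if not cohort:
        raise ValueError("empty cohort")
    out = {
        "genotypes": np.stack([s.genotypes for s in cohort]),
        "exposure": np.array([s.exposure for s in cohort]),
        "event": np.array([1.0 if s.event else 0.0 for s in cohort]),
        "event_code": np.array([s.event_code for s in cohort], dtype=object),
        "time": np.array([s.time for s in cohort]),
    }
    for k in cohort[0].covariates:
        out[k] = np.array([s.covariates[k] for s in cohort])
    return out


def simulate_two_cohorts(config: SimConfig) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Simulate the disjoint exposure and outcome cohorts.

    Fully reproducible from ``config.seed``; the exposure cohort plays the
    role of the genomic cohort the instrument weights come from, the
    outcome cohort supplies events, follow-up and outcome associations.
    """
    exp_arr = simulate_cohort_arrays(config, "exposure")
    out_arr = simulate_cohort_arrays(config, "outcome")
    return _arrays_to_records(exp_arr), _arrays_to_records(out_arr)


def cohort_to_summary_stats(
    cohort: Sequence[SubjectRecord] | dict[str, np.ndarray],
    trait: str,
    variants: Sequence[Variant] | None = None,
    maf_min: float = gwas.MAF_MIN_DEFAULT,
    hwe_min_p: float = gwas.HWE_MIN_P_DEFAULT,
) -> list[AssociationRecord]:
    """QC the panel and scan one trait, producing MR-ready summary statistics.

    ``trait`` is either a continuous column name ("exposure", "sbp", "ldl",
    ...) scanned by linear regression, or "outcome" for a logistic scan of
    the binary event.  Scans adjust for age and sex, mirroring a typical
    biobank GWAS covariate set.  Variants failing MAF/HWE QC are absent
    from the output.
    """
    arr = cohort if isinstance(cohort, dict) else cohort_arrays(cohort)
    G = np.asarray(arr["genotypes"], dtype=float)
    if trait == "outcome":
        y = np.asarray(arr["event"], dtype=float)
        if y.min() == y.max():
            raise ValueError("degenerate outcome: all events or all non-events")
        family = "logistic"
    else:
        if trait not in arr:
            raise KeyError(f"trait {trait!r} not present in cohort")
        y = np.asarray(arr[trait], dtype=float)
        family = "linear"

    J = G.shape[1]
    if variants is None:
        variants = [
            Variant(id=f"rs{j + 1}", chrom="1", pos=10_000 + 137 * j,
                    effect_allele="A", other_allele="G",
                    eaf=float(np.mean(G[:, j]) / 2))
            for j in range(J)
        ]
    report = gwas.qc_filter(G.astype(int), maf_min=maf_min, hwe_min_p=hwe_min_p,
                            variant_ids=[v.id for v in variants])
    keep = report.passed
    covs = np.column_stack([arr["age"], arr["sex"]])
    scan = gwas.association_scan(G[:, keep], y, covariates=covs, family=family,
                                 variants=[variants[j] for j in keep])
    return scan.records
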