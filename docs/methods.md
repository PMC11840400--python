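# Methods

This note records the statistical model behind `mrglyc`, the defaults
and why they were chosen, and the design decisions taken where more
than one defensible construction exists.

## The synthetic two-cohort study

The generator (`mrglyc.synth`) emulates the structure of a two-sample
MR study of fasting serum glucose (FSG) and cardiovascular events: a
genomic "exposure" cohort in which instrument-exposure effects are
estimated, and a disjoint "outcome" cohort supplying events, follow-up
times, ICD-10 codes and instrument-outcome effects.  Per subject `i`
with independent dosages `g_ij ~ Binomial(2, maf_j)`:

    x_i   = μ_x + Σ_j β_j g_ij + c_x U_i + e_i                 (FSG, mg/dL)
    η_i   = f(x_i) + Σ_j α_j g_ij + θ_S (SBP_i − μ_S)
            + θ_L (LDL_i − μ_L) + c_y U_i + covariate terms
    T_i   ~ Exponential(rate = λ₀ exp(η_i)), censored at t_max

`U` is a standard-normal latent confounder shared by FSG, SBP, LDL and
the outcome.  The event indicator is "event time before administrative
censoring", so the binary outcome used by the logistic GWAS and the
survival outcome used by Cox share one linear predictor; with ~8%
cumulative incidence the log-odds and log-hazard scales differ by a few
percent, well inside estimation error at these cohort sizes.

Key defaults (all overridable in `SimConfig`):

| parameter | default | unit | rationale |
|---|---|---|---|
| J (instruments) | 42 | — | size of a realistic glucose instrument panel |
| maf | U(0.05, 0.45) | — | common variants; clears the 0.01 QC line by construction |
| exposure mean / sd | 93.72 / 18.0 | mg/dL | population FSG distribution of a middle-aged East-Asian cohort |
| h² of panel | 0.03 | — | a few percent of variance, typical for a glycaemic score |
| θ (causal effect) | 0.01 | log-odds per mg/dL | OR ≈ 1.105 per 10 mg/dL |
| confounder effects (c_x, c_y) | (+5, −0.25) | mg/dL, log-odds | negative confounding, so the observational HR is *attenuated* relative to the causal OR — the discrepancy pattern the two-arm design exposes |
| secondary exposures | SBP: h²=0.015, θ=0.02/mmHg; LDL: h²=0.08, θ=0.005/(mg/dL) | | weak-SBP / strong-LDL instrument-strength contrast (conditional F ≈ 7 vs ≈ 38 at n = 20k) |
| pleiotropy α_j | none / balanced N(0, 0.01) / directional N(0.02, 0.01) | log-odds per allele | directional mean 0.02 is detectable by the Egger intercept at n = 20k |
| baseline hazard / follow-up | 0.006 per yr / 13 yr | | ~8% cumulative incidence over the follow-up window |
| quadratic curvature | 1.5e-3 | log-odds per (mg/dL)² | the "strong curvature" scenario; sized by a design power analysis targeting ≈90% power for the non-linearity test at n = 5,000 (a J-shaped curve: local per-10 OR ranging ≈0.6 to ≈2 across ±1.5 SD) |

Secondary-exposure instrument effects are drawn mean-zero, so in
univariable MR they act as *balanced* pleiotropy (extra heterogeneity,
no bias) while giving the multivariable model genuine second and third
exposures.  All randomness flows from one integer seed through named
sub-streams (`cohort-exposure`, `cohort-outcome`, `maf`, `alpha`, ...),
so any stage is independently regenerable and reruns are byte-identical.

What the generator does **not** emulate: linkage disequilibrium between
instruments, population structure and relatedness, imputation
uncertainty, genome-scale variant counts, informative censoring,
medication changes during follow-up, and assay error in the exposure.
Passing tests therefore demonstrate internal statistical correctness of
the estimators under the stated model, not robustness to those
real-data features.

## Harmonization

Variants are matched by identifier only.  Swapped effect/other alleles
flip the outcome beta and complement its frequency; any other allele
pair is dropped as a mismatch; palindromic (A/T, C/G) variants with
exposure EAF in (0.42, 0.58) — window w = 0.08 — or with unknown EAF are
dropped as strand-ambiguous.  No frequency-based strand inference is
attempted for non-palindromic variants: silent sign errors are worse
than dropped variants.

## GWAS stage

QC: sample MAF ≥ 0.01 (inclusive) and Hardy-Weinberg χ² p ≥ 1e-6
(exclusion strict).  The HWE test is the 1-df goodness-of-fit χ²
(deterministic and adequate at panel scale; a mid-p exact test would be
the extension for rare variants).  Scans fit trait ~ dosage + age + sex
per variant: OLS for continuous traits, Newton-ML logistic for the
binary event (statsmodels backends; score tolerance 1e-8, 50
iterations).  Degenerate fits — zero residual variance, separation,
non-convergence — are flagged and excluded rather than reported with
meaningless SEs.

## Univariable MR

Default IVW standard errors are multiplicative random-effects with a
floor at the fixed-effect SE: heterogeneity can widen but never narrow
the CI.  MR-Egger orients every variant to γ_j > 0 before regression
(the intercept is orientation-dependent; this is the established
convention) and uses the same floored multiplicative scale.  The
weighted median interpolates at cumulative weight 0.5 over the sorted
ratios with normalized inverse-variance weights; its SE is a parametric
bootstrap (1,000 draws, explicit seed) perturbing both γ and Γ by their
reported SEs.  Wald-ratio SEs are first order (no-measurement-error
approximation); all CIs are Wald-normal; per-10 reporting applies
exp(10·) to estimate and bounds.

## Multivariable MR

MVMR-IVW: weighted least squares of Γ on the K exposure-effect columns
with weights σ_Γ⁻² and no intercept; coefficient covariance from the
weighted information matrix; validity Q = weighted residual sum of
squares on J − K df.  Conditional F for exposure k regresses its
effects on the other exposures' effects (weights σ_jk⁻²) and divides
the weighted residual sum by **J − K + 1**.  Published software differs
on this denominator; the convention is declared in the result metadata
rather than hidden.  Covariances between exposure effect estimates are
taken as zero, as is unavoidable when each exposure's GWAS is available
only as summary statistics.

## Non-linear MR

Stratification is on the IV-free exposure (the residual of exposure on
the weighted allele score), not on raw exposure, to avoid collider
bias; 10 equal-size strata by default (S is a free parameter; no
canonical value exists).  LACE_s is the within-stratum logistic
coefficient of the event on the score divided by the full-cohort linear
coefficient of exposure on the score — the shared denominator
stabilizes the ratio and is exposed as a switch.  Strata with a single
outcome class are excluded with a warning.  Curves are anchored at the
cohort-median exposure.

**Non-linearity test.**  The linear model says the local slope is
constant; the degree-1 fractional-polynomial alternative
g(x) = b₁x + b₂x^p (p ∈ {−2, −1, −0.5, 0, 0.5, 2, 3}, 0 meaning log)
adds one curvature term.  Two naive constructions fail: (i) testing the
*non-nested* one-parameter family b·x^p against the linear model is
degenerate — whenever the true constant slope is non-zero, every
curved power fits worse and the test essentially never rejects; (ii)
referring the likelihood ratio of the *best* power to χ²(1) ignores the
selection over the grid and over-rejects (measured ≈0.087 at nominal
0.05).  The implemented test computes, for each power, the exact
Gaussian score statistic for b₂ (known stratum variances), takes the
maximum squared statistic over the grid, and refers it to the joint
null distribution of the correlated statistics — a multivariate normal
whose correlation matrix is fixed by the design — evaluated by a
deterministic Monte Carlo draw (40,000 samples, fixed internal seed;
p-values are floored at 1/40,000).  Measured size at nominal 5% under
the linear default: 0.055 with binomial error ±0.011.

The piecewise-linear curve integrates stratum LACEs over exposure with
interior knots at midpoints between consecutive stratum means,
anchored to zero at the reference; its pointwise band accumulates
delta-method variances of the integrated slopes.

## Observational stage

ICD-10 endpoint classification uses 3-character prefix ranges: IHD
I20-I25 (AMI = I21-I22), stroke I60-I69 split into hemorrhagic I60-I62
and thrombotic I63/I65-I66 (I64, I67-I69 count only toward total
stroke), other CVD I10-I15, I44-I49, I50, I51, I70-I74, R96; the stroke
subtype boundaries are this package's recorded convention.  Cox models
(lifelines, Efron ties) adjust for age, sex, HDL, LDL, SBP, alcohol and
smoking (model 1) plus BMI, exercise, TG and income (model 2); a crude
no-covariate model is available for oracle tests.  Proportionality is
checked by the score test on the scaled Schoenfeld residual trend
(rank time transform).

## Numerical conventions and degenerate inputs

* Wald p-values with zero SE: 1 if the estimate is 0, else 0.
* Monomorphic variants: HWE p = 1 by convention, then removed by MAF QC.
* Exact-fit regressions (zero residual variance) are flagged, not
  reported with SE 0 (which would violate the record invariant).
* IVW/weighted-median require J ≥ 2 / ≥ 3; Egger J ≥ 3; MVMR J > K;
  fractional polynomial ≥ 4 strata; piecewise ≥ 2.
* Score statistics below 1e-12 are treated as numerically zero, so an
  exactly constant LACE profile reports power 1 and p = 1.

## Problem sizes in the test suite

Simulation-based tests run at the default two-cohort size (20,000 +
20,000) where single-replicate recovery is asserted, at n = 5,000 per
cohort over 50 replicates for the confounding-direction contrast, at
n = 5,000 over 500 (size) and 100 (power) replicates for the
non-linearity calibration, and at the summary-statistic level (50
replicates) for the weighted-median breakdown — sizes chosen so each
property is decided with comfortable statistical margin.  At the
default cohort size the per-10 OR of a single run has a Monte Carlo
spread of roughly ±8% (IVW) and more for Egger; single-run point
estimates should be read with that spread in mind.

## Known limitations

* Two-sample estimators assume non-overlapping cohorts; the generator
  enforces this, the IO layer cannot verify it for user-supplied files.
* The logistic-vs-hazard scale gap (~1/(1−incidence)) is ignored; at
  the default 8% incidence it is far below estimation error.
* MVMR-Egger, outlier-robust MR (MR-PRESSO, mode-based, contamination
  mixture), Steiger filtering, doubly-ranked stratification, and
  survival-outcome non-linear MR are out of scope.
* LD-aware instrument selection is not implemented; instruments are
  assumed independent.
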