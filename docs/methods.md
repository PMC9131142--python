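# Methods

## The estimator

`bioage` implements a cross-sectional biological-age (BA) model of the
Nakamura first-principal-component family. A panel of N age-associated
biomarkers is standardized to mean 0 / unit SD on a reference cohort
(sample SD, n−1 denominator), and the leading eigenvector of their
correlation matrix defines a single aging axis. Three algebraic stages turn
the projection into years:

1. **Score.** BAS = w₀ + Σ wₙxₙ with wₙ = aₙ/σₙ and w₀ = −Σ wₙ·x̄ₙ. Because
   the loadings a are unit-norm and the columns standardized, the training
   score has mean 0 and SD √λ exactly (projection identity).
2. **T-scale.** BA = (BAS/√λ)·σ_CA + mean CA. The score is standardized to
   unit variance *before* scaling. This is the single most consequential
   reading of the method: the literal transcription BA = BAS·σ_CA + mean CA
   omits the √λ division, but the published female/male coefficient sets are
   only consistent with the standardized form (e.g. male FEV1:
   0.431·13.8/√2.25 = 3.965 ≈ the published corrected coefficient 3.96,
   whereas 0.431·13.8 = 5.95 matches nothing). The literal behavior is kept
   available via `tscale(..., standardize=False)` for comparison.
3. **Regression-to-the-mean correction (Dubina).** b is the OLS slope of BA
   on CA on the training sample; BAc = BA + (CA − mean CA)(1 − b). Since
   training BA has SD σ_CA, b equals the BA–CA Pearson correlation, and the
   construction forces, in-sample and exactly: mean BAc = mean CA,
   slope(BAc ~ CA) = 1, and corr(BAc, CA) = 1/√(2 − b²). These identities
   are the package's primary self-checks (tested to 1e−9) and explain the
   published headline correlations: b = 0.80 → 0.86, b = 0.68 → 0.81.

Sex-stratified fitting is the default (the reference models are per-sex);
pooled fitting is allowed with a warning. Eigenvectors are sign-ambiguous,
so orientation is fixed by forcing a named anchor loading non-negative —
total cholesterol by default (it rises with age in the reference table), or
CA itself when the component is fitted with CA included as a check variable.

**Published fixtures.** The female/male models are shipped exactly as
printed: loading tables (with and without CA), eigenvalues (2.79 / 2.25),
score equations, age scales (13.6/41.3 and 13.8/41.1 years), and corrected
equations. The print contains internal inconsistencies that are preserved,
never corrected, and surfaced by `audit_published` / `bioage audit`:

* the male corrected intercept (−70.37 printed vs −75.37 derived from the
  printed parts; σ_CA/√λ = 9.2 exactly, so the expansion is unambiguous);
* the female FEV1 score coefficient (−0.018, which implies an FEV1 SD of
  7.7 L; the printed corrected coefficient −2.03 corresponds to ≈ −0.249);
* female MAP (0.27 vs 0.244) and suPAR (3.24 vs 3.26), consistent with the
  score coefficients having been rounded to 2–3 figures before print.

Derived-vs-printed comparisons elsewhere use a ±0.01 budget, the rounding
noise of 2-decimal printing.

## Screening

The stepwise selection mirrors the published procedure with the printed
boundary conventions: the age-correlation gate is strict on r (|r| > 0.15)
and inclusive on p (p ≤ .05, two-sided from the t transform of r with n−2
df — the method is not stated in the source and this is the standard
choice); redundancy clustering is inclusive (|r| ≥ 0.7); the 99% reference
interval (mean ± 2.96·SD, multiplier as printed even though 2.576 is the
conventional 99% value) flags strictly-outside values and is advisory only.
Clusters are connected components of the thresholded correlation graph —
the deterministic generalization of the pairwise reasoning in the source,
which never encounters chained clusters. Cluster representatives are chosen
by an ordered clinical-priority list (mirroring waist circumference over
waist/hip ratio) and otherwise by the strongest age correlation (mirroring
FEV1 over FVC and FEV1/FVC). The HbA1c-over-fasting-glucose choice in the
source happens at r = 0.29, far below the 0.7 rule, so it is representable
only as a manual override, not a rule. Correlations use complete pairs;
disease-history eligibility is a boolean column honored by a filter, not
inferred from biomarkers. When SBP and DBP both pass the gate and cluster,
the pipeline (default on) synthesizes MAP = SBP/3 + 2·DBP/3, re-screens it
and retires the pressure pair. No multiple-testing correction is applied
across candidates (none is applied in the source).

## Synthetic cohorts

The generator emulates the reference study design, not any individual-level
data (none are deposited). Defaults:

* **Design.** 5 individuals per sex per bin across ten equal-width age bins
  spanning 18–65 y (width 4.7 y — "≈5-year" bins; 47 years is not divisible
  by 5, and equal-width bins keep the design mean/SD of CA at ≈41.5/13.6 y,
  bracketing the reference scale constants 41.3/13.6 and 41.1/13.8). Ages
  are uniform within bins. Default total: 100 individuals.
* **Marginals and trends.** Each biomarker is mean + slope·(age − 41.2) + ε
  with the published pooled mean, SD and per-year slope. The residual SD is
  chosen so the *marginal* SD at the design age distribution equals the
  published SD (residual variance = SD² − slope²·Var(age)), floored at 10%
  of SD² with a warning when the printed slope alone exceeds the printed
  variance — which happens only for the handgrip row, whose printed slope
  (−0.8) lies outside its own printed CI (−0.2 to 0.1) and is stored as
  printed with a data-quality warning.
* **Correlation.** Residuals are multivariate normal with an identity
  correlation matrix except the published SBP–DBP block (r = 0.8135). Other
  real intercorrelations are published only as a figure and are deliberately
  not defaults; the matrix is fully configurable.
* **Sex offsets.** Additive male mean shifts for seven generator columns
  covering the nine-biomarker panel (+6 cm waist, +0.9 L FEV1,
  +5 mL/min/kg VO2max, −0.3 mmol/L HDL, −3500 adiponectin, +4/+2 mmHg
  SBP/DBP). These are package defaults grounded in general physiology — the
  reference table is pooled across sexes and publishes no sex-specific
  marginals, so exact sex-specific generating parameters are unrecoverable.
* **Positivity.** Biomarkers are positive physical quantities; a record
  whose residual vector produces a non-positive value is redrawn as a whole
  (rejection sampling, preserving the joint shape above zero; 100 attempts,
  then an error). For biomarkers whose published mean sits within ~1 SD of
  zero (CRP, leptin) this truncation visibly raises the marginal mean and
  attenuates the slope — an accepted distortion of rows that do not enter
  the final model.

What passing tests on these cohorts show: the algebraic identities of the
estimator, parameter recovery of the generator itself (slope CIs cover the
configured slopes with ≈95% coverage), and the qualitative screening
behavior (strong-slope biomarkers gate, CI-spanning ones rarely do). What
they cannot show: the real panel's intercorrelation structure, hence
quantities that depend on it — the leading eigenvalue of the real data
(2.79/2.25) exceeds what the age trend alone produces (population value
≈2.1 under the default generator), and the real screening counts
(15 gated biomarkers) are not a contract. Non-linear age effects,
longitudinal trajectories and disease subpopulations are out of scope (the
model itself is linear).

## Numerical choices

* Eigendecomposition via `numpy.linalg.eigh` on the correlation matrix;
  verified in tests against an independent power-iteration oracle (1e−8).
* Pearson r / p via `scipy.stats.pearsonr`, OLS via `scipy.stats.linregress`;
  verified against explicit two-pass summation oracles (1e−12).
* Standardization and all SDs use the n−1 denominator consistently, which
  is what makes the in-sample identities exact rather than approximate.
* Complete-case handling: per pair for correlations, per panel for the PCA
  fit; the CA scale (σ_CA, mean CA) is computed on the same complete cases
  as the component.
* Degenerate inputs: zero-variance columns and rank-0 inputs are errors;
  constant biomarkers fail the screening gate with a warning rather than an
  error; a zero-variance difference vector in the paired t test returns a
  flagged degenerate result (p = 1 at zero bias) instead of NaN.
* Bland–Altman limits of agreement use the universal 1.96 multiplier; the
  age difference is CA − BAc (positive = biologically younger). The
  published biases (0.002/−0.006 y) arise from applying *rounded printed*
  coefficients; the full-precision path gives bias 0 by construction, and
  both behaviors are reproducible (`apply_printed_bac` vs a refit).
* Model JSON carries a schema version; √λ (not the sample score SD, equal
  in-sample anyway) is serialized so documents are self-contained.

## Problem sizes

Tests and the acceptance script use the default 100-individual design for
identity checks (they hold at any n to machine precision), 200 per sex ×
50 seeds for the slope-recovery coverage sweep, and 10⁵ draws for the
simulation cross-check of the closed-form corrected correlation — sizes at
which every Monte-Carlo tolerance used is several standard errors wide.
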