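# bioage

Biological-age estimation from physiological biomarkers of healthy aging.

Chronological age (CA) alone does not capture individual differences in the
rate of aging. `bioage` implements a biological-age (BA) estimator built on
the first principal component (1PC) of a panel of physiological biomarkers —
the approach introduced by Nakamura and co-workers and used in a line of
cross-sectional BA studies — together with everything needed to develop and
evaluate such a model: a reference panel of 32 candidate aging biomarkers, a
synthetic-cohort generator, systematic biomarker screening, and agreement
statistics. It ships the published female/male nine-biomarker models (mean
arterial pressure, HbA1c, waist circumference, FEV1, VO2max, adiponectin,
HDL, total cholesterol, suPAR) as ready-to-use fixtures.

## The model

Given biomarkers x₁…x_N standardized on a reference cohort, the 1PC of their
correlation matrix (loadings aₙ, eigenvalue λ) defines a standardized
biological-age score

    BAS = w₀ + Σₙ wₙ xₙ,   wₙ = aₙ / σₙ,   w₀ = −Σₙ wₙ x̄ₙ,

which has mean 0 and SD √λ over the training cohort. The T-scale method
expresses the score in years using the cohort's CA scale (σ_CA, mean CA):

    BA = (BAS / √λ) · σ_CA + mean CA.

Because BA regresses toward the mean (younger people are over-aged, older
people under-aged), the Dubina correction is applied with b the OLS slope of
BA on CA:

    BAc = BA + (CA − mean CA) · (1 − b).

By construction, on the training cohort: mean BAc = mean CA, the slope of
BAc on CA is exactly 1, and corr(BAc, CA) = 1/√(2 − b²) — with the published
b of 0.80 (women) and 0.68 (men) this gives the headline correlations 0.86
and 0.81.

Biomarker selection follows the published stepwise procedure: a 99% reference
interval (mean ± 2.96·SD) for advisory outlier flags, an age-correlation gate
(|r| > 0.15, P ≤ .05), redundancy pruning of clusters with |r| ≥ 0.7 (one
representative per cluster, by clinical priority or strongest age
correlation), and substitution of mean arterial pressure
(MAP = SBP/3 + 2·DBP/3) for the systolic/diastolic pair.

## Worked example

Score an individual with the shipped published female model:

```python
import bioage as ba

model = ba.published_model("female")
record = {"map": 96.0, "hba1c": 35.0, "waist_circumference": 88.0,
          "fev1": 3.1, "vo2max": 33.0, "adiponectin": 12000.0,
          "hdl": 1.7, "total_cholesterol": 5.1, "supar": 2.4}
print(round(ba.predict_bac(model, record, ca=48.0), 1))
```

This prints `54.6`: a 48-year-old woman with this slightly adverse profile
(elevated MAP, HbA1c and waist, reduced FEV1 and VO2max) has a corrected
biological age of 54.6 years — an age difference CA − BAc of −6.6 years,
i.e. biologically older than her calendar age. The uncorrected BA is 53.3
years (`model.ba(record)`), and the correction adds
(48 − 41.3)·(1 − 0.80) = 1.3 years because she is older than the reference
cohort mean.

The full pipeline on a synthetic cohort, from the shell:

```sh
bioage pipeline --seed 0 --out-dir run/
```

writes the cohort, screening table, per-sex model JSONs, predictions and
agreement reports. With seed 0 the female model selects 17 of the screened
biomarkers (λ = 4.33, b = 0.90) and its in-sample evaluation shows slope
1.000000, bias 2e-14 and r = 0.917 — the constructional identities above,
visible in `run/report_female.json`. The subcommands `simulate`, `screen`,
`fit`, `predict`, `evaluate` and `audit` expose each stage separately
(`bioage audit` prints the reconciliation of the published corrected
coefficients against the published score coefficients, including the known
misprints it preserves).

## Synthetic cohorts

No human data are distributed. `bioage.simulate_cohort` emulates the
reference study design — ~100 adults, balanced by sex within ~5-year age
bins over 18–65 y — with each biomarker following its published mean, SD and
per-year age slope, plus configurable residual correlations. This generator
defines the conditions under which the package's statistical guarantees are
tested; see `docs/methods.md` for what it does and does not emulate.

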