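"""Published female/male biological-age models, stored exactly as printed.

These fixtures carry the reference study's printed loading tables, score
equations and corrected-equation coefficients so the estimator can be applied
without refitting, and so the package's coefficient-reconciliation audit can
compare what the printed parts imply against what was printed.

Known internal inconsistencies of the printed equations (all preserved, never
corrected):

* male corrected intercept: printed -70.37, but expanding the printed score
  equation with sigma_CA/sqrt(lambda) = 13.8/1.5 = 9.2 gives ~= -75.37;
* female FEV1 corrected coefficient: printed -2.03, while the printed score
  coefficient -0.018 (itself implausible -- it implies an FEV1 SD of 7.7 L)
  expands to -0.147;
* female MAP (0.27 printed vs 0.244 expanded) and suPAR (3.24 vs 3.26):
  consistent with the score coefficients having been rounded before print.

``audit_published`` reports all of these without failing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import BAModel, PC1Model, CA_COLUMN
from .cohort import canonical_sex

#: Panel order used throughout the printed equations.
PANEL = ("map", "hba1c", "waist_circumference", "fev1", "vo2max",
         "adiponectin", "hdl", "total_cholesterol", "supar")

#: Loading tables for the 1PC, CA excluded (the model-defining fit).
LOADINGS_CA_EXCLUDED = {
    "female": {"map": 0.435, "hba1c": 0.408, "waist_circumference": 0.173,
               "fev1": -0.138, "vo2max": -0.341, "adiponectin": 0.228,
               "hdl": 0.390, "total_cholesterol": 0.467, "supar": 0.238},
    "male": {"map": 0.349, "hba1c": 0.324, "waist_circumference": 0.491,
             "fev1": -0.309, "vo2max": -0.475, "adiponectin": -0.046,
             "hdl": -0.020, "total_cholesterol": 0.3804, "supar": 0.254},
}

#: Loading tables with CA included (aging-factor check), incl. the CA row.
LOADINGS_CA_INCLUDED = {
    "female": {"ca": 0.473, "map": 0.392, "hba1c": 0.348,
               "waist_circumference": 0.144, "fev1": -0.164, "vo2max": -0.287,
               "adiponectin": 0.199, "hdl": 0.346, "total_cholesterol": 0.405,
               "supar": 0.220},
    "male": {"ca": 0.515, "map": 0.294, "hba1c": 0.352,
             "waist_circumference": 0.378, "fev1": -0.340, "vo2max": -0.321,
             "adiponectin": 0.078, "hdl": 0.127, "total_cholesterol": 0.337,
             "supar": 0.167},
}

EIGENVALUE = {"female": 2.79, "male": 2.25}
EIGENVALUE_CA_INCLUDED = {"female": 3.50, "male": 2.90}
EXPLAINED_PCT = {"female": 30.96, "male": 25.04}
EXPLAINED_PCT_CA_INCLUDED = {"female": 35.04, "male": 28.96}

#: Printed contribution percentages (CA-excluded model).
CONTRIBUTIONS_PCT = {
    "female": {"map": 18.9, "hba1c": 16.7, "waist_circumference": 3.0,
               "fev1": 1.9, "vo2max": 11.6, "adiponectin": 5.2, "hdl": 15.2,
               "total_cholesterol": 21.8, "supar": 5.7},
    "male": {"map": 12.2, "hba1c": 10.5, "waist_circumference": 24.1,
             "fev1": 9.5, "vo2max": 22.6, "adiponectin": 0.2, "hdl": 0.04,
             "total_cholesterol": 14.5, "supar": 6.4},
}

#: Printed score equations (BAS = w0 + sum w_n x_n).
BAS_COEFFICIENTS = {
    "female": {"intercept": -11.04, "map": 0.03, "hba1c": 0.126,
               "waist_circumference": 0.018, "fev1": -0.018, "vo2max": -0.053,
               "adiponectin": 3.205e-5, "hdl": 0.909,
               "total_cholesterol": 0.500, "supar": 0.400},
    "male": {"intercept": -11.23, "map": 0.037, "hba1c": 0.103,
             "waist_circumference": 0.066, "fev1": -0.431, "vo2max": -0.067,
             "adiponectin": -1.058e-5, "hdl": -0.062,
             "total_cholesterol": 0.442, "supar": 0.828},
}

#: Age scale: BA = BAS_std * sigma_CA + mean_CA.
AGE_SCALE = {"female": (13.6, 41.3), "male": (13.8, 41.1)}

#: Printed corrected equations (BAc), including the CA term.
BAC_COEFFICIENTS = {
    "female": {"intercept": -56.67, "map": 0.27, "hba1c": 1.02,
               "waist_circumference": 0.1453, "fev1": -2.03, "vo2max": -0.43,
               "adiponectin": 0.0003, "hdl": 7.39, "total_cholesterol": 4.06,
               "supar": 3.24, "ca": 0.20},
    "male": {"intercept": -70.37, "map": 0.34, "hba1c": 0.95,
             "waist_circumference": 0.60, "fev1": -3.96, "vo2max": -0.62,
             "adiponectin": -9.73e-5, "hdl": -0.57, "total_cholesterol": 4.06,
             "supar": 7.61, "ca": 0.32},
}


def published_b_slope(sex: str) -> float:
    """The correction slope implied by the printed CA coefficient, b = 1 - c_CA."""
    return 1.0 - BAC_COEFFICIENTS[canonical_sex(sex)]["ca"]


def published_model(sex: str) -> BAModel:
    """The printed estimator as a ready-to-use :class:`BAModel`.

    Score coefficients, loadings, eigenvalue and age scale are stored exactly
    as printed.  Per-biomarker training SDs are implied (sigma_n = a_n / w_n);
    training means were not published and are carried as NaN -- predictions
    never need them because the printed w0 already absorbs the centering.
    """
    sex = canonical_sex(sex)
    loadings = np.array([LOADINGS_CA_EXCLUDED[sex][n] for n in PANEL])
    bas = BAS_COEFFICIENTS[sex]
    w = np.array([bas[n] for n in PANEL])
    with np.errstate(divide="ignore"):
        implied_sd = loadings / w
    pc1 = PC1Model(
        biomarker_names=list(PANEL), loadings=loadings,
        eigenvalue=EIGENVALUE[sex],
        train_mean=np.full(len(PANEL), np.nan),
        train_sd=implied_sd, sign_anchor="total_cholesterol",
    )
    sigma_ca, mean_ca = AGE_SCALE[sex]
    return BAModel(pc1=pc1, w0=bas["intercept"], w=w, sigma_ca=sigma_ca,
                   mean_ca=mean_ca, b_slope=published_b_slope(sex),
                   sex_label=sex, standardize=True)


def apply_printed_bac(sex: str, data: pd.DataFrame) -> np.ndarray:
    """Evaluate the printed corrected equation verbatim (rounded coefficients).

    ``data`` needs the panel columns plus ``age``.  This is the path that
    reproduces the small published Bland-Altman biases (0.002 / -0.006 y);
    the full-precision refit path gives bias 0 by construction.
    """
    sex = canonical_sex(sex)
    coefs = BAC_COEFFICIENTS[sex]
    out = np.full(len(data), coefs["intercept"], dtype=float)
    for name in PANEL:
        out += coefs[name] * data[name].to_numpy(dtype=float)
    out += coefs["ca"] * data["age"].to_numpy(dtype=float)
    return out


def audit_published(sex: str | None = None, tol: float = 0.01) -> pd.DataFrame:
    """Reconcile printed corrected coefficients with the printed score parts.

    For each biomarker the derived value is w_n * sigma_CA / sqrt(lambda)
    (intercept: w0 * sigma_CA / sqrt(lambda) + mean_CA * b); ``flagged`` marks
    absolute discrepancies beyond ``tol`` (the printing-rounding budget).
    The audit only reports -- printed values are never altered.
    """
    sexes = [canonical_sex(sex)] if sex else ["female", "male"]
    rows = []
    for s in sexes:
        sigma_ca, mean_ca = AGE_SCALE[s]
        scale = sigma_ca / np.sqrt(EIGENVALUE[s])
        b = published_b_slope(s)
        bas, bac = BAS_COEFFICIENTS[s], BAC_COEFFICIENTS[s]
        for name in PANEL:
            derived = bas[name] * scale
            rows.append((s, name, derived, bac[name]))
        rows.append((s, CA_COLUMN, 1.0 - b, bac["ca"]))
        rows.append((s, "intercept", bas["intercept"] * scale + mean_ca * b,
                     bac["intercept"]))
    table = pd.DataFrame(rows, columns=["sex", "term", "derived", "printed"])
    table["abs_diff"] = (table["derived"] - table["printed"]).abs()
    table["flagged"] = table["abs_diff"] > tol
    return table
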