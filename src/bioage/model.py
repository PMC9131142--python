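"""First-principal-component biological-age model.

The estimator compresses a panel of N age-associated biomarkers into a single
aging axis and expresses it in years:

1. standardize each biomarker to mean 0 / unit SD on the training cohort;
2. take the leading eigenvector (loadings ``a_n``, eigenvalue ``lambda``) of
   the correlation matrix -- the first principal component (1PC);
3. biological age score: ``BAS = w0 + sum_n w_n x_n`` with ``w_n = a_n /
   sigma_n`` and ``w0 = -sum_n w_n mean_n``, so the training mean of BAS is 0
   and its SD is sqrt(lambda);
4. T-scale to years: ``BA = BAS / sqrt(lambda) * sigma_CA + mean_CA`` -- BAS
   is standardized to unit variance before scaling, so training BA has the
   CA mean and SD (see docs/methods.md for why the sqrt(lambda) division is
   the reading consistent with the published coefficients; the literal scale
   ``BA = BAS * sigma_CA + mean_CA`` is available via ``standardize=False``);
5. regression-to-the-mean correction: with ``b`` the OLS slope of BA on CA,
   ``BAc = BA + (CA - mean_CA) * (1 - b)``.  In-sample this forces
   mean(BAc) = mean(CA), slope(BAc ~ CA) = 1 and
   corr(BAc, CA) = 1 / sqrt(2 - b^2), exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, canonical_sex
from .errors import DomainError, ModelSchemaError

SCHEMA_VERSION = 1

#: Default sign anchors: the 1PC eigenvector is sign-ambiguous, so orientation
#: is fixed by forcing a named loading non-negative.  Total cholesterol rises
#: with age in the reference data, so anchoring it positive orients the axis
#: "older = larger score"; with CA included, CA itself is the natural anchor.
DEFAULT_ANCHOR = "total_cholesterol"
CA_COLUMN = "ca"


# ---------------------------------------------------------------------------
# PC1
# ---------------------------------------------------------------------------

@dataclass
class PC1Model:
    """Leading principal component of standardized biomarkers.

    ``biomarker_names`` may include the pseudo-variable ``"ca"`` when the
    component was fitted with chronological age included (used to check that
    the 1PC behaves as a general aging factor).
    """

    biomarker_names: list[str]
    loadings: np.ndarray
    eigenvalue: float
    train_mean: np.ndarray
    train_sd: np.ndarray
    sign_anchor: str
    n_train: int = 0

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.train_mean = np.asarray(self.train_mean, dtype=float)
        self.train_sd = np.asarray(self.train_sd, dtype=float)

    @property
    def explained_variance_fraction(self) -> float:
        return self.eigenvalue / len(self.biomarker_names)

    @property
    def includes_ca(self) -> bool:
        return CA_COLUMN in self.biomarker_names


def fit_pc1(
    cohort: CohortTable,
    biomarkers: Sequence[str],
    include_ca: bool = False,
    sign_anchor: str | None = None,
) -> PC1Model:
    """Fit the first principal component on complete cases.

    Columns are standardized by their training mean and SD (ddof=1); the 1PC
    is the leading eigenvector of the resulting correlation matrix, oriented
    so the ``sign_anchor`` loading is non-negative.
    """
    biomarkers = list(biomarkers)
    cols = biomarkers + ([CA_COLUMN] if include_ca else [])
    X = cohort.data[biomarkers].to_numpy(dtype=float)
    if include_ca:
        X = np.column_stack([X, cohort.age.to_numpy(dtype=float)])
    ok = ~np.isnan(X).any(axis=1)
    n = int(ok.sum())
    if n < len(cols) + 2:
        per_col = {c: int(np.isnan(X[:, i]).sum()) for i, c in enumerate(cols)}
        raise DomainError(
            f"need >= {len(cols) + 2} complete records, got {n}; "
            f"missing per column: {per_col}"
        )
    X = X[ok]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        flat = [c for c, s in zip(cols, sd) if s == 0]
        raise DomainError(f"zero variance in columns {flat}")
    Z = (X - mean) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lam = float(evals[-1])
    vec = evecs[:, -1]
    if lam <= 0:
        raise DomainError("degenerate input: leading eigenvalue not positive")

    if sign_anchor is None:
        sign_anchor = CA_COLUMN if include_ca else (
            DEFAULT_ANCHOR if DEFAULT_ANCHOR in cols else cols[0]
        )
    if sign_anchor not in cols:
        raise DomainError(f"sign anchor {sign_anchor!r} not among fitted columns")
    if vec[cols.index(sign_anchor)] < 0:
        vec = -vec
    return PC1Model(
        biomarker_names=cols, loadings=vec, eigenvalue=lam,
        train_mean=mean, train_sd=sd, sign_anchor=sign_anchor, n_train=n,
    )


def contributions(pc1: PC1Model | Mapping[str, float] | pd.Series) -> pd.Series:
    """Percentage contribution of each variable: 100 * a_n^2 / sum_k a_k^2.

    Accepts a fitted :class:`PC1Model` or a plain name -> loading mapping
    (e.g. a published loading column).  Invariant under a global sign flip;
    sums to 100.
    """
    if isinstance(pc1, PC1Model):
        names, a = pc1.biomarker_names, pc1.loadings
    else:
        s = pd.Series(pc1, dtype=float)
        names, a = list(s.index), s.to_numpy()
    a = np.asarray(a, dtype=float)
    total = float((a**2).sum())
    if total == 0:
        raise DomainError("all loadings are zero")
    return pd.Series(100.0 * a**2 / total, index=names, name="contribution_pct")


# ---------------------------------------------------------------------------
# BAS / BA / BAc
# ---------------------------------------------------------------------------

def fit_bas(pc1: PC1Model) -> tuple[float, np.ndarray]:
    """Score coefficients: w_n = a_n / sigma_n, w0 = -sum w_n mean_n.

    Requires a component fitted without CA among the variables.  Over the
    training cohort the resulting score has mean 0 and SD sqrt(lambda).
    """
    if pc1.includes_ca:
        raise DomainError("score coefficients require a CA-free component")
    if not np.all(np.isfinite(pc1.train_mean)):
        raise DomainError("training means unavailable for this component")
    w = pc1.loadings / pc1.train_sd
    w0 = -float(w @ pc1.train_mean)
    return w0, w


def tscale(bas, sigma_ca: float, mean_ca: float, eigenvalue: float,
           standardize: bool = True):
    """Convert a score to years on the cohort's age scale.

    Default (``standardize=True``) divides by sqrt(eigenvalue) first so the
    score enters with unit variance: BA = BAS/sqrt(lambda)*sigma_CA + mean_CA.
    ``standardize=False`` applies the literal scale BA = BAS*sigma_CA+mean_CA.
    """
    if eigenvalue <= 0:
        raise DomainError("eigenvalue must be positive")
    bas = np.asarray(bas, dtype=float)
    scale = sigma_ca / np.sqrt(eigenvalue) if standardize else sigma_ca
    out = bas * scale + mean_ca
    return float(out) if out.ndim == 0 else out


def fit_correction(ba, ca) -> float:
    """OLS slope of biological age on chronological age (the Dubina ``b``).

    When training BA is scaled to the CA SD, this slope equals the Pearson
    correlation between BA and CA.
    """
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(ba) < 3:
        raise DomainError("need >= 3 records")
    if np.ptp(ca) == 0:
        raise DomainError("zero CA variance")
    # two-pass covariance form of the OLS slope
    return float(np.cov(ba, ca, ddof=1)[0, 1] / np.var(ca, ddof=1))


def implied_corr_bac_ca(b_slope: float) -> float:
    """Training-sample correlation between corrected age and CA: 1/sqrt(2-b^2).

    Follows from the construction: corrected age adds (1-b) of the centered CA
    to a score whose SD equals the CA SD and whose correlation with CA is b.
    """
    if abs(b_slope) > 1:
        raise DomainError("|b| must be <= 1")
    return 1.0 / np.sqrt(2.0 - b_slope**2)


@dataclass
class BAModel:
    """Complete biological-age estimator for one sex stratum."""

    pc1: PC1Model
    w0: float
    w: np.ndarray
    sigma_ca: float
    mean_ca: float
    b_slope: float
    sex_label: str = ""
    standardize: bool = True

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.pc1.biomarker_names)

    @property
    def _year_scale(self) -> float:
        return (self.sigma_ca / np.sqrt(self.pc1.eigenvalue)
                if self.standardize else self.sigma_ca)

    @property
    def corrected_coefficients(self) -> dict[str, float]:
        """Year-scale expansion of the corrected equation.

        coefficient_n = w_n * sigma_CA / sqrt(lambda); the CA coefficient is
        1 - b; the intercept collects w0 and the centering terms.
        """
        s = self._year_scale
        coefs = {name: float(wn * s) for name, wn in zip(self.biomarker_names, self.w)}
        coefs[CA_COLUMN] = 1.0 - self.b_slope
        coefs["intercept"] = float(self.w0 * s + self.mean_ca * self.b_slope)
        return coefs

    # -- prediction --------------------------------------------------------
    def _matrix(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            missing_cols = [n for n in self.biomarker_names if n not in data.columns]
            if missing_cols:
                raise DomainError(f"missing biomarker columns: {missing_cols}")
            X = data[self.biomarker_names].to_numpy(dtype=float)
        else:
            try:
                X = np.array([[float(data[n]) for n in self.biomarker_names]])
            except KeyError as exc:
                raise DomainError(f"missing biomarker: {exc.args[0]!r}") from None
        bad = np.isnan(X)
        if bad.any():
            names = [self.biomarker_names[j] for j in np.unique(np.nonzero(bad)[1])]
            raise DomainError(f"missing values for biomarkers: {names}")
        return X

    def bas(self, data) -> np.ndarray:
        X = self._matrix(data)
        return self.w0 + X @ self.w

    def ba(self, data) -> np.ndarray:
        return tscale(self.bas(data), self.sigma_ca, self.mean_ca,
                      self.pc1.eigenvalue, standardize=self.standardize)

    def bac(self, data, ca) -> np.ndarray:
        ca = np.asarray(ca, dtype=float)
        return self.ba(data) + (ca - self.mean_ca) * (1.0 - self.b_slope)

    def predict(self, cohort: CohortTable) -> pd.DataFrame:
        """Per-record scores: id, ca, bas, ba, bac, age_diff (= ca - bac)."""
        bas = self.bas(cohort.data)
        ba = tscale(bas, self.sigma_ca, self.mean_ca, self.pc1.eigenvalue,
                    standardize=self.standardize)
        ca = cohort.age.to_numpy(dtype=float)
        bac = ba + (ca - self.mean_ca) * (1.0 - self.b_slope)
        return pd.DataFrame({
            "id": cohort.data["id"], "sex": cohort.sex, "ca": ca,
            "bas": bas, "ba": ba, "bac": bac, "age_diff": ca - bac,
        })


def predict_bac(model: BAModel, record: Mapping[str, float], ca: float | None = None) -> float:
    """Corrected biological age for a single record.

    ``record`` maps biomarker name -> value and may carry the chronological
    age under ``"ca"`` or ``"age"`` if not given separately.
    """
    if ca is None:
        ca = record.get(CA_COLUMN, record.get("age"))
        if ca is None:
            raise DomainError("chronological age required")
    return float(model.bac(record, float(ca))[0])


def fit_ba_model(
    cohort: CohortTable,
    biomarkers: Sequence[str],
    sex: str | None = None,
    sign_anchor: str | None = None,
    standardize: bool = True,
) -> BAModel:
    """Fit the full estimator on one cohort (optionally one sex stratum)."""
    if sex is not None:
        cohort = cohort.subset_sex(sex)
        label = canonical_sex(sex)
    else:
        label = "pooled"
    pc1 = fit_pc1(cohort, biomarkers, include_ca=False, sign_anchor=sign_anchor)
    w0, w = fit_bas(pc1)
    # CA statistics over the same complete cases used for the component
    X = cohort.data[list(biomarkers)].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    ca = cohort.age.to_numpy(dtype=float)[ok]
    sigma_ca = float(ca.std(ddof=1))
    mean_ca = float(ca.mean())
    bas = w0 + X[ok] @ w
    ba = tscale(bas, sigma_ca, mean_ca, pc1.eigenvalue, standardize=standardize)
    b = fit_correction(ba, ca)
    return BAModel(pc1=pc1, w0=w0, w=w, sigma_ca=sigma_ca, mean_ca=mean_ca,
                   b_slope=b, sex_label=label, standardize=standardize)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_model(model: BAModel) -> str:
    """Lossless JSON document for a fitted estimator."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "sex_label": model.sex_label,
        "standardize": model.standardize,
        "w0": model.w0,
        "w": model.w.tolist(),
        "sigma_ca": model.sigma_ca,
        "mean_ca": model.mean_ca,
        "b_slope": model.b_slope,
        "pc1": {
            "biomarker_names": model.pc1.biomarker_names,
            "loadings": model.pc1.loadings.tolist(),
            "eigenvalue": model.pc1.eigenvalue,
            "train_mean": model.pc1.train_mean.tolist(),
            "train_sd": model.pc1.train_sd.tolist(),
            "sign_anchor": model.pc1.sign_anchor,
            "n_train": model.pc1.n_train,
        },
    }
    return json.dumps(doc, indent=2)


def deserialize_model(doc: str) -> BAModel:
    try:
        data = json.loads(doc)
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"malformed model document: {exc}") from exc
    try:
        version = data["schema_version"]
        if version != SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unsupported schema version {version} (supported: {SCHEMA_VERSION})"
            )
        p = data["pc1"]
        pc1 = PC1Model(
            biomarker_names=list(p["biomarker_names"]),
            loadings=np.array(p["loadings"], dtype=float),
            eigenvalue=float(p["eigenvalue"]),
            train_mean=np.array(p["train_mean"], dtype=float),
            train_sd=np.array(p["train_sd"], dtype=float),
            sign_anchor=p["sign_anchor"],
            n_train=int(p.get("n_train", 0)),
        )
        return BAModel(
            pc1=pc1, w0=float(data["w0"]), w=np.array(data["w"], dtype=float),
            sigma_ca=float(data["sigma_ca"]), mean_ca=float(data["mean_ca"]),
            b_slope=float(data["b_slope"]), sex_label=data.get("sex_label", ""),
            standardize=bool(data.get("standardize", True)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelSchemaError(f"incomplete model document: {exc}") from exc
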