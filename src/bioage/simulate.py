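"""Synthetic cohort generator.

Emulates the reference study design: equal numbers of women and men per
~5-year age bin spanning 18-65 y, with each biomarker following a linear age
trend whose slope, marginal mean and marginal SD match the published reference
table, plus multivariate-normal residuals with a configurable correlation
structure.  Residual SDs are derived so that the *marginal* SD at the design's
age distribution equals the published SD:

    residual_var = table1_sd^2 - slope^2 * Var(age),

floored at 10% of table1_sd^2 (with a warning) when the age trend alone would
exceed the published variance.  Biomarkers are positive physical quantities;
records whose residual draw produces a non-positive value are rejected and
redrawn as a whole vector (truncation by rejection, preserving the joint
shape above zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .errors import ConfigurationWarning, DomainError
from .registry import BiomarkerSpec, SBP_DBP_CORRELATION, table1_registry

#: Age at which biomarker means equal their published (pooled) reference means.
AGE_CENTER = 41.2

#: Default additive mean shifts for males, covering the nine-biomarker panel
#: (MAP enters through SBP/DBP).  Package defaults from general physiology;
#: the reference table is pooled across sexes and publishes no sex-specific
#: marginals.
DEFAULT_SEX_OFFSETS: dict[str, float] = {
    "waist_circumference": 6.0,
    "fev1": 0.9,
    "vo2max": 5.0,
    "hdl": -0.3,
    "adiponectin": -3500.0,
    "sbp": 4.0,
    "dbp": 2.0,
}

_MAX_RESAMPLES = 100


def default_age_bins(low: float = 18.0, high: float = 65.0, n_bins: int = 10) -> list[tuple[float, float]]:
    """Equal-width age bins spanning [low, high) (default ten ~5-year bins)."""
    edges = np.linspace(low, high, n_bins + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def default_residual_correlation(names: Sequence[str]) -> np.ndarray:
    """Identity residual correlation except the published SBP-DBP block."""
    names = list(names)
    corr = np.eye(len(names))
    if "sbp" in names and "dbp" in names:
        i, j = names.index("sbp"), names.index("dbp")
        corr[i, j] = corr[j, i] = SBP_DBP_CORRELATION
    return corr


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Defaults reproduce the reference design: 5 per sex per bin over ten bins
    -> 100 individuals, mean age ~41.5 y, SD ~13.6 y.
    """

    n_per_sex_per_bin: int = 5
    age_bins: list[tuple[float, float]] = field(default_factory=default_age_bins)
    registry: list[BiomarkerSpec] = field(default_factory=lambda: table1_registry(warn=False))
    residual_correlation: np.ndarray | None = None
    sex_offsets: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_OFFSETS))
    seed: int = 0

    def __post_init__(self):
        if self.n_per_sex_per_bin < 1:
            raise DomainError("n_per_sex_per_bin must be >= 1")
        bins = sorted(self.age_bins)
        for (a1, b1), (a2, b2) in zip(bins[:-1], bins[1:]):
            if b1 > a2:
                raise DomainError("age bins overlap")
        for a, b in bins:
            if not (0 < a < b):
                raise DomainError(f"bad age bin ({a}, {b})")
        self.age_bins = bins
        names = [s.name for s in self.registry]
        if self.residual_correlation is None:
            self.residual_correlation = default_residual_correlation(names)
        corr = np.asarray(self.residual_correlation, dtype=float)
        k = len(names)
        if corr.shape != (k, k):
            raise DomainError(f"residual_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise DomainError("residual_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise DomainError("residual_correlation diagonal must be 1")
        if np.abs(corr).max() > 1 + 1e-12:
            raise DomainError("residual_correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise DomainError("residual_correlation must be positive semi-definite")
        self.residual_correlation = corr
        unknown = set(self.sex_offsets) - set(names)
        if unknown:
            raise DomainError(f"sex_offsets name unknown biomarkers: {sorted(unknown)}")

    @property
    def design_age_variance(self) -> float:
        """Variance of age under equal counts per bin, uniform within bins."""
        mids = np.array([(a + b) / 2 for a, b in self.age_bins])
        widths = np.array([b - a for a, b in self.age_bins])
        mean = mids.mean()
        return float(np.mean(mids**2 + widths**2 / 12) - mean**2)


def _residual_sds(config: SimulationConfig) -> np.ndarray:
    var_age = config.design_age_variance
    out = []
    for spec in config.registry:
        resid_var = spec.table1_sd**2 - spec.table1_slope_per_year**2 * var_age
        floor = 0.1 * spec.table1_sd**2
        if resid_var < floor:
            warnings.warn(
                f"{spec.name}: age trend alone exceeds the target marginal "
                f"variance; residual variance floored at 10% of SD^2",
                ConfigurationWarning, stacklevel=3,
            )
            resid_var = floor
        out.append(np.sqrt(resid_var))
    return np.array(out)


def simulate_cohort(config: SimulationConfig | None = None) -> CohortTable:
    """Draw one synthetic cohort; deterministic under a fixed config and seed."""
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(config.seed)
    names = [s.name for s in config.registry]
    means = np.array([s.table1_mean for s in config.registry])
    slopes = np.array([s.table1_slope_per_year for s in config.registry])
    positive = np.array([s.positive for s in config.registry])
    resid_sd = _residual_sds(config)
    cov = config.residual_correlation * np.outer(resid_sd, resid_sd)
    # eigh-based factor: tolerant of semi-definite correlation targets
    evals, evecs = np.linalg.eigh(cov)
    factor = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    rows = []
    idx = 0
    for low, high in config.age_bins:
        for sex in ("female", "male"):
            ages = rng.uniform(low, high, size=config.n_per_sex_per_bin)
            for age in ages:
                mu = means + slopes * (age - AGE_CENTER)
                if sex == "male":
                    for name, off in config.sex_offsets.items():
                        mu[names.index(name)] += off
                for attempt in range(_MAX_RESAMPLES):
                    eps = factor @ rng.standard_normal(len(names))
                    values = mu + eps
                    if not (positive & (values <= 0)).any():
                        break
                else:
                    bad = [n for n, v in zip(names, mu + eps) if v <= 0]
                    raise DomainError(
                        f"could not draw positive values for {bad} in "
                        f"{_MAX_RESAMPLES} attempts; check config"
                    )
                rows.append({"id": f"S{idx:04d}", "sex": sex, "age": float(age),
                             **dict(zip(names, values))})
                idx += 1
    return CohortTable(pd.DataFrame(rows), registry=list(config.registry))


def summarize_cohort(cohort: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-biomarker mean, SD, and OLS age slope with a (1-alpha) CI.

    Mirrors the layout of the published reference table so that simulated and
    configured parameters can be compared directly.  Biomarkers with fewer
    than 3 non-missing values are excluded with a warning.
    """
    records = []
    age = cohort.age.to_numpy(dtype=float)
    for name in cohort.biomarker_names:
        y = cohort.values(name).to_numpy(dtype=float)
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < 3:
            warnings.warn(f"{name}: fewer than 3 values; excluded from summary",
                          UserWarning, stacklevel=2)
            continue
        yv, xv = y[ok], age[ok]
        mean, sd = float(yv.mean()), float(yv.std(ddof=1))
        if np.ptp(xv) == 0 or sd == 0:
            slope, lo, hi = 0.0, 0.0, 0.0
        else:
            fit = stats.linregress(xv, yv)
            tcrit = stats.t.ppf(1 - alpha / 2, n - 2) if n > 2 else np.inf
            slope = float(fit.slope)
            half = tcrit * fit.stderr
            lo, hi = slope - half, slope + half
        records.append({"biomarker": name, "n": n, "mean": mean, "sd": sd,
                        "slope_per_year": slope, "ci_low": float(lo), "ci_high": float(hi)})
    columns = ["biomarker", "n", "mean", "sd", "slope_per_year", "ci_low", "ci_high"]
    return pd.DataFrame(records, columns=columns).set_index("biomarker")
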