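"""Reference panel of candidate aging biomarkers.

The registry carries, for each of the 32 candidate biomarkers measured in the
reference cohort of 100 healthy adults (18-65 y), the published cross-sectional
mean, SD and per-year linear age slope with its 95% CI.  These numbers
parameterize the synthetic-cohort generator and anchor the screening defaults.

``priority_rank`` encodes clinical priority used to pick a representative when
highly intercorrelated biomarkers form a redundancy cluster: the nine panel
biomarkers of the final biological-age model rank first.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from typing import Sequence

from .errors import DataQualityWarning

INCREASES = "increases_with_age"
DECREASES = "decreases_with_age"
UNKNOWN = "unknown"

_DIRECTIONS = (INCREASES, DECREASES, UNKNOWN)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Metadata for one candidate biomarker.

    Parameters
    ----------
    name : canonical machine name (CSV column name).
    label : human-readable label.
    units : measurement units (metadata only; no conversion is ever applied).
    table1_mean, table1_sd : published cohort mean and SD.
    table1_slope_per_year : published linear regression slope on age.
    slope_ci : 95% CI of the slope, as printed.
    priority_rank : unique clinical-priority rank (1 = highest).
    expected_direction : sign of the age trend when the published CI excludes 0.
    positive : the quantity is physically non-negative (used by the simulator).
    """

    name: str
    label: str
    units: str
    table1_mean: float
    table1_sd: float
    table1_slope_per_year: float
    slope_ci: tuple[float, float]
    priority_rank: int
    expected_direction: str = UNKNOWN
    positive: bool = True
    domain: str = ""

    def __post_init__(self):
        if self.table1_sd <= 0:
            raise ValueError(f"{self.name}: SD must be positive")
        if self.expected_direction not in _DIRECTIONS:
            raise ValueError(f"{self.name}: bad direction {self.expected_direction!r}")
        lo, hi = self.slope_ci
        if lo > hi:
            raise ValueError(f"{self.name}: CI bounds reversed")
        if not (lo <= 0.0 <= hi):
            want = INCREASES if self.table1_slope_per_year > 0 else DECREASES
            if self.expected_direction != want:
                raise ValueError(
                    f"{self.name}: expected_direction inconsistent with slope sign"
                )

    @property
    def slope_consistent(self) -> bool:
        """Whether the printed point slope lies inside its own printed CI."""
        lo, hi = self.slope_ci
        return lo <= self.table1_slope_per_year <= hi


def _spec(name, label, units, mean, sd, slope, ci, rank, direction, domain):
    return BiomarkerSpec(
        name=name, label=label, units=units, table1_mean=mean, table1_sd=sd,
        table1_slope_per_year=slope, slope_ci=ci, priority_rank=rank,
        expected_direction=direction, domain=domain,
    )


# Published reference table, stored exactly as printed (including the handgrip
# row whose point slope falls outside its own CI -- see data_quality_report).
_TABLE1 = [
    # name, label, units, mean, sd, slope, (ci_lo, ci_hi), rank, direction, domain
    _spec("weight", "Weight", "kg", 75.7, 13.1, 0.03, (-0.2, 0.2), 11, UNKNOWN, "body_composition"),
    _spec("waist_circumference", "Waist circumference", "cm", 83.4, 9.8, 0.2, (0.05, 0.3), 1, INCREASES, "body_composition"),
    _spec("hip_circumference", "Hip circumference", "cm", 101.4, 7.1, -0.001, (-0.1, 0.1), 12, UNKNOWN, "body_composition"),
    _spec("waist_hip_ratio", "Waist/hip ratio", "ratio", 0.8, 0.07, 0.002, (0.001, 0.003), 13, INCREASES, "body_composition"),
    _spec("fat_mass_pct", "Fat mass", "%", 26.8, 8.3, 0.09, (-0.03, 0.2), 14, UNKNOWN, "body_composition"),
    _spec("muscle_mass", "Muscle mass", "kg", 52.8, 10.9, -0.05, (-0.2, 0.1), 15, UNKNOWN, "body_composition"),
    _spec("fasting_glucose", "Fasting blood glucose", "mmol/L", 5.1, 0.4, 0.01, (0.004, 0.015), 16, INCREASES, "metabolic"),
    _spec("hba1c", "HbA1c", "mmol/mol", 32.8, 3.2, 0.12, (0.08, 0.16), 2, INCREASES, "metabolic"),
    _spec("ages", "Advanced glycation end products", "AU", 1.8, 0.5, 0.027, (0.022, 0.031), 17, INCREASES, "metabolic"),
    _spec("insulin", "Insulin", "pmol/L", 44.4, 25.3, 0.05, (-0.32, 0.42), 18, UNKNOWN, "metabolic"),
    _spec("triglycerides", "Triglycerides", "mmol/L", 0.9, 0.4, 0.002, (-0.004, 0.008), 19, UNKNOWN, "metabolic"),
    _spec("free_fatty_acids", "Free fatty acids", "umol/L", 440.0, 212.0, 2.36, (-0.72, 5.46), 20, UNKNOWN, "metabolic"),
    _spec("leptin", "Leptin", "pg/mL", 8411.0, 9472.0, -60.0, (-199.8, 79.9), 21, UNKNOWN, "metabolic"),
    _spec("adiponectin", "Adiponectin", "mg/mL", 11515.0, 6490.0, 106.6, (13.4, 199.8), 7, INCREASES, "metabolic"),
    _spec("hdl", "HDL cholesterol", "mmol/L", 1.5, 0.4, 0.01, (0.006, 0.017), 6, INCREASES, "metabolic"),
    _spec("ldl", "LDL cholesterol", "mmol/L", 2.8, 0.8, 0.02, (0.01, 0.03), 22, INCREASES, "metabolic"),
    _spec("total_cholesterol", "Total cholesterol", "mmol/L", 4.5, 0.9, 0.03, (0.02, 0.04), 5, INCREASES, "metabolic"),
    _spec("tc_hdl_ratio", "TC/HDL ratio", "ratio", 3.1, 0.9, 0.003, (-0.01, 0.02), 23, UNKNOWN, "metabolic"),
    _spec("crp", "C-reactive protein", "mg/L", 1.6, 3.4, -0.04, (-0.09, 0.01), 24, UNKNOWN, "immune"),
    _spec("supar", "suPAR", "ng/mL", 2.09, 0.5, 0.01, (0.003, 0.017), 8, INCREASES, "immune"),
    _spec("hemoglobin", "Hemoglobin", "mmol/L", 8.7, 0.8, 0.004, (-0.01, 0.02), 25, UNKNOWN, "blood"),
    _spec("hematocrit", "Hematocrit", "%", 41.6, 3.8, 0.03, (-0.03, 0.09), 26, UNKNOWN, "blood"),
    _spec("dbp", "Diastolic blood pressure", "mmHg", 78.0, 10.1, 0.4, (0.3, 0.5), 10, INCREASES, "cardiorespiratory"),
    _spec("sbp", "Systolic blood pressure", "mmHg", 124.2, 16.7, 0.6, (0.3, 0.8), 9, INCREASES, "cardiorespiratory"),
    _spec("fev1", "FEV1", "L", 3.9, 0.9, -0.02, (-0.04, -0.01), 3, DECREASES, "cardiorespiratory"),
    _spec("fvc", "FVC", "L", 4.9, 1.0, -0.02, (-0.04, -0.01), 27, DECREASES, "cardiorespiratory"),
    _spec("fev1_fvc_ratio", "FEV1/FVC ratio", "%", 77.8, 11.6, -0.13, (-0.20, -0.05), 28, DECREASES, "cardiorespiratory"),
    _spec("vo2max", "VO2max", "mL/min/kg", 39.3, 8.11, -0.18, (-0.28, -0.06), 4, DECREASES, "physical"),
    _spec("sit_to_stand", "30-s sit-to-stand", "stands", 23.4, 5.2, -0.07, (-0.14, 0.01), 29, UNKNOWN, "physical"),
    _spec("handgrip_strength", "Handgrip strength", "kg", 36.0, 9.4, -0.8, (-0.2, 0.1), 30, UNKNOWN, "physical"),
    _spec("biceps_strength", "Biceps strength", "kg", 35.0, 11.5, -0.1, (-0.3, 0.03), 31, UNKNOWN, "physical"),
    _spec("quadriceps_strength", "Quadriceps strength", "Nm", 152.4, 51.3, -0.7, (-1.4, 0.1), 32, UNKNOWN, "physical"),
]

#: The nine biomarkers of the final biological-age model (MAP replaces SBP/DBP).
MODEL_PANEL = (
    "map", "hba1c", "waist_circumference", "fev1", "vo2max",
    "adiponectin", "hdl", "total_cholesterol", "supar",
)

#: Published intercorrelation between systolic and diastolic pressure.
SBP_DBP_CORRELATION = 0.8135


def table1_registry(warn: bool = True) -> list[BiomarkerSpec]:
    """Return the 32 candidate biomarkers with published means, SDs and slopes.

    With ``warn=True`` a :class:`DataQualityWarning` is emitted for any row
    whose printed point slope lies outside its own printed CI (the handgrip
    row); values are nevertheless returned exactly as printed.
    """
    registry = list(_TABLE1)
    if warn:
        for spec in registry:
            if not spec.slope_consistent:
                warnings.warn(
                    f"{spec.name}: printed slope {spec.table1_slope_per_year} lies "
                    f"outside its printed CI {spec.slope_ci}; stored as printed",
                    DataQualityWarning,
                    stacklevel=2,
                )
    return registry


def map_spec(sbp_dbp_corr: float = SBP_DBP_CORRELATION) -> BiomarkerSpec:
    """Derived mean-arterial-pressure biomarker, MAP = SBP/3 + 2*DBP/3.

    Mean and slope follow by linearity from the SBP and DBP reference rows; the
    SD additionally needs their correlation (published value 0.8135).
    """
    by_name = {s.name: s for s in _TABLE1}
    sbp, dbp = by_name["sbp"], by_name["dbp"]
    mean = sbp.table1_mean / 3 + 2 * dbp.table1_mean / 3
    slope = sbp.table1_slope_per_year / 3 + 2 * dbp.table1_slope_per_year / 3
    var = (
        (sbp.table1_sd / 3) ** 2
        + (2 * dbp.table1_sd / 3) ** 2
        + 2 * (sbp.table1_sd / 3) * (2 * dbp.table1_sd / 3) * sbp_dbp_corr
    )
    lo = sbp.slope_ci[0] / 3 + 2 * dbp.slope_ci[0] / 3
    hi = sbp.slope_ci[1] / 3 + 2 * dbp.slope_ci[1] / 3
    return BiomarkerSpec(
        name="map", label="Mean arterial pressure", units="mmHg",
        table1_mean=mean, table1_sd=math.sqrt(var),
        table1_slope_per_year=slope, slope_ci=(lo, hi),
        priority_rank=33, expected_direction=INCREASES,
        domain="cardiorespiratory",
    )


def full_registry(warn: bool = False) -> list[BiomarkerSpec]:
    """Table-1 registry plus the derived MAP entry."""
    return table1_registry(warn=warn) + [map_spec()]


def get_spec(registry: Sequence[BiomarkerSpec], name: str) -> BiomarkerSpec:
    for spec in registry:
        if spec.name == name:
            return spec
    raise KeyError(name)


def data_quality_report(registry: Sequence[BiomarkerSpec]) -> list[str]:
    """Human-readable list of internal inconsistencies in the reference table."""
    return [
        f"{s.name}: slope {s.table1_slope_per_year} outside CI {s.slope_ci}"
        for s in registry
        if not s.slope_consistent
    ]


def registry_to_json(registry: Sequence[BiomarkerSpec]) -> str:
    """Serialize a registry to an editable JSON document."""
    return json.dumps([asdict(s) for s in registry], indent=2)


def registry_from_json(doc: str) -> list[BiomarkerSpec]:
    items = json.loads(doc)
    out = []
    for item in items:
        item["slope_ci"] = tuple(item["slope_ci"])
        out.append(BiomarkerSpec(**item))
    ranks = [s.priority_rank for s in out]
    if len(set(ranks)) != len(ranks):
        raise ValueError("priority_rank values must be unique within a registry")
    return out
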