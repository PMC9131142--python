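"""Cohort data model and CSV I/O.

A cohort is a wide table with one row per individual: an opaque ``id``, a
``sex`` category (female/male), chronological ``age`` in years, and zero or
more numeric biomarker columns whose names must appear in an accompanying
:class:`~bioage.registry.BiomarkerSpec` registry.  Missing biomarker values
are carried as NaN; empty cells and "NA" parse as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CellParseError, CohortFormatError, CohortValidationError
from .registry import BiomarkerSpec, full_registry

MANDATORY_COLUMNS = ("id", "sex", "age")

#: Accepted sex spellings (case-insensitive) -> canonical category.
SEX_CODES = {
    "female": "female", "f": "female", "w": "female", "women": "female", "woman": "female",
    "male": "male", "m": "male", "men": "male", "man": "male",
}

MISSING_TOKENS = {"", "na", "nan", "n/a"}


@dataclass
class CohortTable:
    """Validated cohort: ``data`` has columns id, sex, age, then biomarkers.

    Optional non-biomarker metadata columns (currently only the boolean
    ``eligible`` flag used by the screening stage) are preserved.
    """

    data: pd.DataFrame
    registry: list[BiomarkerSpec] = field(default_factory=full_registry)

    META_COLUMNS = ("eligible",)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def biomarker_names(self) -> list[str]:
        skip = set(MANDATORY_COLUMNS) | set(self.META_COLUMNS)
        return [c for c in self.data.columns if c not in skip]

    @property
    def age(self) -> pd.Series:
        return self.data["age"]

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    def values(self, name: str) -> pd.Series:
        return self.data[name]

    def subset_sex(self, sex: str) -> "CohortTable":
        sex = canonical_sex(sex)
        return CohortTable(self.data[self.data["sex"] == sex].copy(), self.registry)

    def missing_count(self, name: str) -> int:
        return int(self.data[name].isna().sum())

    # -- validation --------------------------------------------------------
    def _validate(self):
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise CohortFormatError(f"mandatory column {col!r} missing")
        ids = df["id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise CohortValidationError(f"duplicate ids: {dupes}")
        df["id"] = ids
        df["sex"] = df["sex"].map(lambda s: canonical_sex(s))
        age = pd.to_numeric(df["age"], errors="coerce")
        if age.isna().any():
            raise CohortValidationError("non-numeric age values")
        if ((age <= 0) | (age >= 130)).any():
            bad = df.loc[(age <= 0) | (age >= 130), "id"].tolist()
            raise CohortValidationError(f"age out of (0, 130) for ids {bad}")
        df["age"] = age.astype(float)

        known = {s.name for s in self.registry}
        for name in self.biomarker_names:
            if name not in known:
                raise CohortValidationError(
                    f"biomarker column {name!r} not in the registry"
                )
            col = pd.to_numeric(df[name], errors="coerce")
            bad = col.isna() & df[name].notna() & ~df[name].astype(str).str.strip().str.lower().isin(MISSING_TOKENS)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise CellParseError(
                    f"unparseable value {df[name].iloc[i]!r} in column {name!r}, row {i}",
                    row=i, column=name,
                )
            df[name] = col.astype(float)


def canonical_sex(value) -> str:
    key = str(value).strip().lower()
    try:
        return SEX_CODES[key]
    except KeyError:
        raise CohortValidationError(f"unrecognized sex code {value!r}") from None


def read_cohort(path, registry: Sequence[BiomarkerSpec] | None = None) -> CohortTable:
    """Read and validate a cohort CSV (columns ``id,sex,age,<biomarkers...>``).

    Columns not found in the registry are reported with a warning and dropped
    from the biomarker set (kept only if they are recognized metadata columns).
    """
    registry = list(registry) if registry is not None else full_registry()
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortFormatError(f"cannot parse {path}: {exc}") from exc
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise CohortFormatError(f"mandatory column {col!r} missing from {path}")

    known = {s.name for s in registry} | set(MANDATORY_COLUMNS) | set(CohortTable.META_COLUMNS)
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        warnings.warn(
            f"ignoring columns not in the biomarker registry: {unknown}",
            UserWarning, stacklevel=2,
        )
        raw = raw.drop(columns=unknown)

    df = raw.copy()
    # empty strings / NA tokens -> NaN before numeric validation
    for col in df.columns:
        if col in ("id", "sex"):
            continue
        df[col] = df[col].map(
            lambda v: np.nan if str(v).strip().lower() in MISSING_TOKENS else v
        )
    if "eligible" in df.columns:
        df["eligible"] = df["eligible"].map(_parse_bool)
    return CohortTable(df, registry)


def _parse_bool(v):
    if isinstance(v, float) and np.isnan(v):
        return True
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise CellParseError(f"unparseable eligibility flag {v!r}", column="eligible")


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV; missing cells become empty fields.

    Values are written with ``repr`` round-trip precision so that
    ``read_cohort(write_cohort(c))`` reproduces ``c`` exactly.
    """
    df = cohort.data.copy()
    df.to_csv(path, index=False, float_format=None, na_rep="")
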