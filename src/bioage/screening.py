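"""Systematic stepwise biomarker selection.

The selection pipeline mirrors the reference procedure:

1. eligibility filter (disease-history exclusions, as a boolean column);
2. advisory outlier flags from a 99% reference interval (mean +/- 2.96*SD);
3. an age-correlation gate: keep biomarkers with |r| > 0.15 and P <= .05
   (Pearson, two-sided, complete pairs);
4. redundancy pruning: biomarkers with pairwise |r| >= 0.7 form clusters
   (connected components), and one representative per cluster is kept, chosen
   by clinical priority, else by the strongest age correlation;
5. optional mean-arterial-pressure synthesis: when systolic and diastolic
   pressure both pass the gate and cluster together, MAP = SBP/3 + 2*DBP/3 is
   computed, re-screened, and SBP/DBP are retired in its favor.

Boundary conventions are exactly as published: strict on r (|r| > 0.15),
inclusive on p (p <= .05), inclusive on clustering (|r| >= 0.7), strict
"outside" for interval flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import CohortTable
from .errors import CohortValidationError, DomainError
from .registry import map_spec

REFERENCE_INTERVAL_K = 2.96  # published 99% reference-interval multiplier


# ---------------------------------------------------------------------------
# derived variables
# ---------------------------------------------------------------------------

def derive_map(sbp, dbp):
    """Mean arterial pressure, MAP = SBP/3 + 2*DBP/3 (mmHg).

    Accepts scalars or arrays; requires sbp >= dbp > 0 elementwise (NaNs pass
    through as missing).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    both = ~(np.isnan(sbp) | np.isnan(dbp))
    if np.any(dbp[both] <= 0):
        raise DomainError("pressures must be positive")
    if np.any(sbp[both] < dbp[both]):
        raise DomainError("diastolic pressure exceeds systolic pressure")
    out = sbp / 3.0 + 2.0 * dbp / 3.0
    return float(out) if out.ndim == 0 else out


def add_map_column(cohort: CohortTable) -> CohortTable:
    """Return a cohort with a derived ``map`` column and registry entry."""
    df = cohort.data.copy()
    df["map"] = derive_map(df["sbp"].to_numpy(), df["dbp"].to_numpy())
    registry = list(cohort.registry)
    if "map" not in {s.name for s in registry}:
        registry.append(map_spec())
    return CohortTable(df, registry)


# ---------------------------------------------------------------------------
# outlier reference interval
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Advisory per-value outlier flags from the 99% reference interval."""

    table: pd.DataFrame  # columns: id, biomarker, value, low, high, flagged
    k: float = REFERENCE_INTERVAL_K

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def reference_interval_flags(
    cohort: CohortTable, biomarkers: Sequence[str] | None = None,
    k: float = REFERENCE_INTERVAL_K,
) -> OutlierReport:
    """Flag values strictly outside mean +/- k*SD, computed from the cohort.

    Flags are advisory only -- extreme values are meant to be assessed
    individually, never removed automatically.  A biomarker with zero SD
    produces no flags.
    """
    biomarkers = list(biomarkers) if biomarkers is not None else cohort.biomarker_names
    rows = []
    for name in biomarkers:
        v = cohort.values(name).to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            continue
        mean, sd = v[ok].mean(), v[ok].std(ddof=1)
        low, high = mean - k * sd, mean + k * sd
        for i in np.flatnonzero(ok):
            rows.append({
                "id": cohort.data["id"].iloc[i], "biomarker": name,
                "value": v[i], "low": low, "high": high,
                "flagged": bool(sd > 0 and (v[i] < low or v[i] > high)),
            })
    return OutlierReport(pd.DataFrame(rows, columns=["id", "biomarker", "value", "low", "high", "flagged"]), k=k)


# ---------------------------------------------------------------------------
# correlation gate
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Per-biomarker screening state.

    ``table`` columns: r_with_age, p_value, n, passed_gate, cluster_id,
    selected, exclusion_reason.  ``selected`` implies ``passed_gate``; within
    a cluster exactly one member is selected unless a manual override forces
    otherwise.
    """

    table: pd.DataFrame
    r_min: float = 0.15
    alpha: float = 0.05
    r_cluster: float = 0.7

    @property
    def gated(self) -> list[str]:
        return self.table.index[self.table["passed_gate"]].tolist()

    @property
    def selected(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    def to_json_dict(self) -> dict:
        return {
            "params": {"r_min": self.r_min, "alpha": self.alpha,
                       "r_cluster": self.r_cluster},
            "biomarkers": self.table.reset_index().to_dict(orient="records"),
        }


def pearson_with_age(cohort: CohortTable, name: str) -> tuple[float, float, int]:
    """Pearson r (and two-sided p from the t transform) of a biomarker vs age."""
    y = cohort.values(name).to_numpy(dtype=float)
    x = cohort.age.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 4:
        raise DomainError(f"{name}: need >= 4 complete pairs, got {n}")
    if np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), n


def correlation_screen(
    cohort: CohortTable, candidates: Sequence[str] | None = None,
    r_min: float = 0.15, alpha: float = 0.05,
) -> ScreeningResult:
    """Age-correlation gate: pass iff |r| > r_min and p <= alpha.

    Constant biomarkers have undefined r and fail the gate with a warning.
    """
    candidates = list(candidates) if candidates is not None else cohort.biomarker_names
    rows = {}
    for name in candidates:
        r, p, n = pearson_with_age(cohort, name)
        if np.isnan(r):
            warnings.warn(f"{name}: correlation undefined (constant); fails gate",
                          UserWarning, stacklevel=2)
            passed = False
        else:
            passed = abs(r) > r_min and p <= alpha
        rows[name] = {"r_with_age": r, "p_value": p, "n": n,
                      "passed_gate": passed, "cluster_id": pd.NA,
                      "selected": False,
                      "exclusion_reason": "none" if passed else "weak_age_correlation"}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "biomarker"
    return ScreeningResult(table, r_min=r_min, alpha=alpha)


# ---------------------------------------------------------------------------
# redundancy pruning
# ---------------------------------------------------------------------------

def pairwise_correlations(cohort: CohortTable, names: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations on complete pairs."""
    sub = cohort.data[list(names)].astype(float)
    return sub.corr(method="pearson", min_periods=2)


def redundancy_prune(
    cohort: CohortTable,
    gated: Sequence[str],
    r_cluster: float = 0.7,
    priority: Sequence[str] = (),
    manual_overrides: Mapping[str, str] | None = None,
    screen: ScreeningResult | None = None,
) -> ScreeningResult:
    """Cluster gated biomarkers at |pairwise r| >= r_cluster and pick one each.

    Clusters are connected components of the thresholded correlation graph.
    The representative is the highest-priority member when any member appears
    in ``priority`` (an ordered list, first = highest), otherwise the member
    with the largest |r with age|.  ``manual_overrides`` maps biomarker ->
    "include"/"exclude" and wins over both rules.
    """
    gated = list(gated)
    overrides = dict(manual_overrides or {})
    bad = set(overrides) - set(gated)
    if bad:
        raise CohortValidationError(f"overrides name un-gated biomarkers: {sorted(bad)}")
    for name, action in overrides.items():
        if action not in ("include", "exclude"):
            raise CohortValidationError(f"override for {name!r} must be include/exclude")

    if screen is None:
        screen = correlation_screen(cohort, gated, r_min=-1.0, alpha=1.0)
    table = screen.table.copy()
    table["cluster_id"] = pd.NA
    table["selected"] = False

    if gated:
        corr = pairwise_correlations(cohort, gated).to_numpy()
        adj = (np.abs(corr) >= r_cluster) & ~np.eye(len(gated), dtype=bool)
        adj &= ~np.isnan(corr)
        _, labels = connected_components(csr_matrix(adj), directed=False)
        rank = {name: i for i, name in enumerate(priority)}
        for cid in np.unique(labels):
            members = [gated[i] for i in np.flatnonzero(labels == cid)]
            in_priority = [m for m in members if m in rank]
            if in_priority:
                rep = min(in_priority, key=lambda m: rank[m])
            else:
                rep = max(members, key=lambda m: abs(table.loc[m, "r_with_age"]))
            for m in members:
                table.loc[m, "cluster_id"] = int(cid)
                if m == rep:
                    table.loc[m, "selected"] = True
                    table.loc[m, "exclusion_reason"] = "none"
                else:
                    table.loc[m, "selected"] = False
                    table.loc[m, "exclusion_reason"] = "redundant"

    for name, action in overrides.items():
        table.loc[name, "selected"] = action == "include"
        table.loc[name, "exclusion_reason"] = "none" if action == "include" else "manual"

    return ScreeningResult(table, r_min=screen.r_min, alpha=screen.alpha,
                           r_cluster=r_cluster)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def filter_eligible(cohort: CohortTable) -> CohortTable:
    """Drop records whose ``eligible`` flag is False (disease-history exclusions)."""
    if "eligible" not in cohort.data.columns:
        return cohort
    keep = cohort.data["eligible"].astype(bool)
    df = cohort.data[keep].drop(columns=["eligible"])
    return CohortTable(df.copy(), cohort.registry)


def screen_cohort(
    cohort: CohortTable,
    candidates: Sequence[str] | None = None,
    r_min: float = 0.15,
    alpha: float = 0.05,
    r_cluster: float = 0.7,
    priority: Sequence[str] | None = None,
    manual_overrides: Mapping[str, str] | None = None,
    synthesize_map: bool = True,
) -> tuple[ScreeningResult, CohortTable]:
    """Run the full selection pipeline; returns the result and the (possibly
    MAP-augmented) cohort the selected biomarkers refer to."""
    cohort = filter_eligible(cohort)
    if priority is None:
        priority = [s.name for s in sorted(cohort.registry, key=lambda s: s.priority_rank)]
    screen = correlation_screen(cohort, candidates, r_min=r_min, alpha=alpha)
    gated = screen.gated

    if synthesize_map and "sbp" in gated and "dbp" in gated:
        corr = pairwise_correlations(cohort, ["sbp", "dbp"]).iloc[0, 1]
        if abs(corr) >= r_cluster:
            cohort = add_map_column(cohort)
            rescreen = correlation_screen(cohort, ["map"], r_min=r_min, alpha=alpha)
            screen.table.loc["map"] = rescreen.table.loc["map"]
            for name in ("sbp", "dbp"):
                screen.table.loc[name, "passed_gate"] = False
                screen.table.loc[name, "exclusion_reason"] = "redundant"
            gated = screen.gated
            priority = ["map" if p == "sbp" else p for p in priority if p != "dbp"]

    result = redundancy_prune(cohort, gated, r_cluster=r_cluster,
                              priority=priority, manual_overrides=manual_overrides,
                              screen=screen)
    return result, cohort
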