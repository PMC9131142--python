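import warnings

import numpy as np
import pandas as pd
import pytest

import bioage as ba


@pytest.fixture(scope="session")
def default_cohort():
    """100-record synthetic cohort under the default study design (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ba.simulate_cohort(ba.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def cohort_with_map(default_cohort):
    return ba.add_map_column(default_cohort)


@pytest.fixture(scope="session")
def female_model(cohort_with_map):
    return ba.fit_ba_model(cohort_with_map, list(ba.MODEL_PANEL), sex="female")


def make_cohort(columns: dict, registry=None, sex=None):
    """Build a small cohort from raw column arrays (age under 'age')."""
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({
        "id": [f"r{i}" for i in range(n)],
        "sex": sex if sex is not None else ["female", "male"] * (n // 2) + ["female"] * (n % 2),
        **columns,
    })
    if registry is None:
        names = [c for c in columns if c != "age"]
        registry = [synthetic_spec(name, rank=i + 1) for i, name in enumerate(names)]
    return ba.CohortTable(df, registry)


def synthetic_spec(name, mean=10.0, sd=2.0, slope=0.0, ci=(-1.0, 1.0), rank=1):
    """Minimal synthetic biomarker metadata for fixture cohorts."""
    return ba.BiomarkerSpec(
        name=name, label=name, units="au", table1_mean=mean, table1_sd=sd,
        table1_slope_per_year=slope, slope_ci=ci, priority_rank=rank,
        positive=False,
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force; never reuse library calls
# from the code paths they check)
# ---------------------------------------------------------------------------

def power_iteration_leading_eig(mat, iters=10000, tol=1e-14):
    """Leading eigenpair by plain power iteration on a symmetric PSD matrix."""
    mat = np.asarray(mat, dtype=float)
    v = np.ones(mat.shape[0]) / np.sqrt(mat.shape[0])
    lam = 0.0
    for _ in range(iters):
        w = mat @ v
        norm = np.sqrt((w * w).sum())
        w /= norm
        lam_new = w @ mat @ w
        if abs(lam_new - lam) < tol:
            v, lam = w, lam_new
            break
        v, lam = w, lam_new
    return lam, v


def two_pass_pearson(x, y):
    """Pearson r from explicit two-pass mean/covariance sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def brute_force_see(ca, bac):
    """SEE from an explicit normal-equation OLS fit and residual loop."""
    ca = np.asarray(ca, dtype=float)
    bac = np.asarray(bac, dtype=float)
    n = len(ca)
    mx, my = sum(ca) / n, sum(bac) / n
    slope = sum((a - mx) * (b - my) for a, b in zip(ca, bac)) / sum((a - mx) ** 2 for a in ca)
    intercept = my - slope * mx
    ss = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(ca, bac))
    return np.sqrt(ss / (n - 2))


def signflip_paired_p(d, n_perm=20000, rng=None):
    """Two-sided paired test p-value by random sign flips of the differences."""
    d = np.asarray(d, dtype=float)
    rng = rng or np.random.default_rng(0)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    stats = np.abs((signs * d).mean(axis=1))
    return (1 + (stats >= obs - 1e-15).sum()) / (n_perm + 1)
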