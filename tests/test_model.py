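import json

import numpy as np
import pytest

import bioage as ba
from bioage.errors import DomainError, ModelSchemaError
from conftest import make_cohort, power_iteration_leading_eig, synthetic_spec


# ---------------------------------------------------------------------------
# PC1 extraction
# ---------------------------------------------------------------------------

def test_perfectly_correlated_pair():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 50)
    c = make_cohort({"age": np.linspace(20, 60, 50), "u": x, "v": x.copy()},
                    registry=[synthetic_spec("u", rank=1), synthetic_spec("v", rank=2)])
    pc1 = ba.fit_pc1(c, ["u", "v"], sign_anchor="u")
    assert pc1.eigenvalue == pytest.approx(2.0, abs=1e-12)
    assert pc1.explained_variance_fraction == pytest.approx(1.0, abs=1e-12)
    assert np.abs(pc1.loadings) == pytest.approx(np.full(2, 1 / np.sqrt(2)), abs=1e-12)
    assert pc1.loadings[0] >= 0  # anchored


def test_independent_columns_limit():
    rng = np.random.default_rng(1)
    n, k = 4000, 5
    cols = {"age": rng.uniform(20, 65, n)}
    registry = []
    for i in range(k):
        cols[f"m{i}"] = rng.normal(0, 1, n)
        registry.append(synthetic_spec(f"m{i}", rank=i + 1))
    pc1 = ba.fit_pc1(make_cohort(cols, registry=registry), list(cols)[1:],
                     sign_anchor="m0")
    assert pc1.eigenvalue == pytest.approx(1.0, abs=0.15)
    assert pc1.explained_variance_fraction == pytest.approx(1 / k, abs=0.05)


def test_loadings_unit_norm_and_anchor(cohort_with_map):
    pc1 = ba.fit_pc1(cohort_with_map, list(ba.MODEL_PANEL))
    assert np.sum(pc1.loadings**2) == pytest.approx(1.0, abs=1e-9)
    assert pc1.sign_anchor == "total_cholesterol"
    assert pc1.loadings[list(ba.MODEL_PANEL).index("total_cholesterol")] >= 0
    assert pc1.explained_variance_fraction == pc1.eigenvalue / 9


def test_eigenpair_matches_power_iteration_oracle(cohort_with_map):
    pc1 = ba.fit_pc1(cohort_with_map, list(ba.MODEL_PANEL))
    sub = cohort_with_map.data[list(ba.MODEL_PANEL)].dropna()
    z = (sub - sub.mean()) / sub.std(ddof=1)
    corr = (z.T @ z).to_numpy() / (len(z) - 1)
    lam, vec = power_iteration_leading_eig(corr)
    assert pc1.eigenvalue == pytest.approx(lam, abs=1e-8)
    assert np.abs(vec @ pc1.loadings) == pytest.approx(1.0, abs=1e-8)


def test_ca_included_fit_anchors_on_age(cohort_with_map):
    pc1 = ba.fit_pc1(cohort_with_map, list(ba.MODEL_PANEL), include_ca=True)
    assert pc1.includes_ca
    assert pc1.sign_anchor == "ca"
    assert len(pc1.biomarker_names) == 10
    assert pc1.loadings[pc1.biomarker_names.index("ca")] >= 0


def test_degenerate_inputs_rejected():
    c = make_cohort({"age": np.linspace(20, 60, 10), "m": np.full(10, 3.0)},
                    registry=[synthetic_spec("m")])
    with pytest.raises(DomainError, match="zero variance"):
        ba.fit_pc1(c, ["m"])
    few = make_cohort({"age": [20.0, 30.0], "m": [1.0, 2.0]},
                      registry=[synthetic_spec("m")])
    with pytest.raises(DomainError, match="complete records"):
        ba.fit_pc1(few, ["m"])


# ---------------------------------------------------------------------------
# contributions
# ---------------------------------------------------------------------------

def test_contributions_sum_and_sign_invariance(cohort_with_map):
    pc1 = ba.fit_pc1(cohort_with_map, list(ba.MODEL_PANEL))
    c1 = ba.contributions(pc1)
    assert c1.sum() == pytest.approx(100.0, abs=1e-9)
    flipped = ba.contributions(dict(zip(pc1.biomarker_names, -pc1.loadings)))
    assert np.allclose(c1.to_numpy(), flipped.to_numpy(), atol=1e-12)


def test_single_variable_contribution_is_total():
    assert ba.contributions({"only": 0.7}).iloc[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# score, T-scale, correction
# ---------------------------------------------------------------------------

def test_single_biomarker_score_coefficients():
    pc1 = ba.PC1Model(biomarker_names=["m"], loadings=np.array([1.0]),
                      eigenvalue=1.0, train_mean=np.array([10.0]),
                      train_sd=np.array([2.0]), sign_anchor="m")
    w0, w = ba.fit_bas(pc1)
    assert w == pytest.approx([0.5])
    assert w0 == pytest.approx(-5.0)
    assert w0 + w[0] * 12.0 == pytest.approx(1.0)


def test_training_score_centered_with_sd_sqrt_lambda(cohort_with_map, female_model):
    m = female_model
    w0, w = ba.fit_bas(m.pc1)
    assert w0 == pytest.approx(m.w0, abs=1e-12)
    assert np.allclose(w, m.w)
    preds = m.predict(cohort_with_map.subset_sex("female"))
    assert preds["bas"].mean() == pytest.approx(0.0, abs=1e-9)
    assert preds["bas"].std(ddof=1) == pytest.approx(np.sqrt(m.pc1.eigenvalue), abs=1e-9)
    assert preds["ba"].mean() == pytest.approx(m.mean_ca, abs=1e-9)
    assert preds["ba"].std(ddof=1) == pytest.approx(m.sigma_ca, abs=1e-9)


def test_tscale_center_and_published_coefficient_scale():
    assert ba.tscale(0.0, 13.6, 41.3, 2.79) == 41.3
    # printed score coefficients scale into printed corrected coefficients
    assert round(0.103 * 13.8 / np.sqrt(2.25), 2) == 0.95   # HbA1c, male
    assert round(0.067 * 13.8 / np.sqrt(2.25), 2) == 0.62   # VO2max, male
    assert ba.tscale(1.0, 13.8, 41.1, 2.25) == pytest.approx(41.1 + 13.8 / 1.5)
    # literal (non-standardized) mode
    assert ba.tscale(1.0, 13.8, 41.1, 2.25, standardize=False) == pytest.approx(54.9)


def test_fit_correction_identity_and_null():
    ca = np.linspace(20, 65, 40)
    assert ba.fit_correction(ca, ca) == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    noise = rng.normal(40, 13, 5000)
    ca_big = rng.uniform(20, 65, 5000)
    assert ba.fit_correction(noise, ca_big) == pytest.approx(0.0, abs=0.05)
    with pytest.raises(DomainError, match="CA variance"):
        ba.fit_correction(ca[:5], np.full(5, 40.0))


@pytest.mark.parametrize("b,expected", [(1.0, 1.0), (0.80, 0.86), (0.68, 0.81)])
def test_implied_corrected_correlation(b, expected):
    assert round(ba.implied_corr_bac_ca(b), 2) == expected


def test_implied_correlation_domain():
    with pytest.raises(DomainError):
        ba.implied_corr_bac_ca(1.2)


def test_implied_correlation_matches_simulation_oracle():
    """Direct construction oracle: draw (BA, CA) with corr b and equal SDs,
    apply the correction, measure the correlation."""
    rng = np.random.default_rng(7)
    n = 200_000
    for b in (0.8, 0.68, 0.3):
        ca = rng.normal(41, 13.7, n)
        ba_years = 41 + b * (ca - 41) + np.sqrt(1 - b**2) * 13.7 * rng.standard_normal(n)
        bac = ba_years + (ca - 41) * (1 - b)
        measured = np.corrcoef(bac, ca)[0, 1]
        assert ba.implied_corr_bac_ca(b) == pytest.approx(measured, abs=0.005)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_correction_vanishes_at_mean_age(female_model):
    record = {n: female_model.pc1.train_mean[i]
              for i, n in enumerate(female_model.biomarker_names)}
    ba_years = float(female_model.ba(record)[0])
    bac = ba.predict_bac(female_model, record, ca=female_model.mean_ca)
    assert bac == pytest.approx(ba_years, abs=1e-9)


def test_no_correction_when_b_is_one(female_model):
    import dataclasses
    m = dataclasses.replace(female_model, b_slope=1.0)
    record = dict(zip(m.biomarker_names, m.pc1.train_mean + 0.3 * m.pc1.train_sd))
    assert ba.predict_bac(m, record, ca=25.0) == pytest.approx(float(m.ba(record)[0]))


def test_missing_biomarker_named_in_error(female_model):
    record = dict(zip(female_model.biomarker_names, female_model.pc1.train_mean))
    del record["hba1c"]
    with pytest.raises(DomainError, match="hba1c"):
        ba.predict_bac(female_model, record, ca=40.0)
    record["hba1c"] = np.nan
    with pytest.raises(DomainError, match="hba1c"):
        ba.predict_bac(female_model, record, ca=40.0)


def test_in_sample_regression_slope_is_one(cohort_with_map):
    for sex in ("female", "male"):
        m = ba.fit_ba_model(cohort_with_map, list(ba.MODEL_PANEL), sex=sex)
        preds = m.predict(cohort_with_map.subset_sex(sex))
        fit = np.polyfit(preds["ca"], preds["bac"], 1)
        assert fit[0] == pytest.approx(1.0, abs=1e-9)
        assert preds["age_diff"].to_numpy() == pytest.approx(
            (preds["ca"] - preds["bac"]).to_numpy())


def test_corrected_coefficient_expansion_consistent(female_model):
    """Evaluating the expanded year-scale equation must equal the staged
    score -> T-scale -> correction path."""
    m = female_model
    coefs = m.corrected_coefficients
    record = dict(zip(m.biomarker_names, m.pc1.train_mean + 0.7 * m.pc1.train_sd))
    ca = 33.0
    expanded = coefs["intercept"] + coefs["ca"] * ca + sum(
        coefs[n] * record[n] for n in m.biomarker_names)
    assert expanded == pytest.approx(ba.predict_bac(m, record, ca=ca), abs=1e-9)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_round_trip_published_model():
    m = ba.published_model("female")
    back = ba.deserialize_model(ba.serialize_model(m))
    assert back.biomarker_names == m.biomarker_names
    assert back.w0 == m.w0
    assert np.array_equal(back.w, m.w)
    assert (back.sigma_ca, back.mean_ca, back.b_slope) == (m.sigma_ca, m.mean_ca, m.b_slope)
    assert back.pc1.eigenvalue == m.pc1.eigenvalue


def test_round_trip_preserves_predictions(female_model):
    back = ba.deserialize_model(ba.serialize_model(female_model))
    rng = np.random.default_rng(3)
    for _ in range(100):
        record = dict(zip(female_model.biomarker_names,
                          female_model.pc1.train_mean
                          + rng.normal(0, 1, 9) * female_model.pc1.train_sd))
        ca = float(rng.uniform(18, 65))
        assert ba.predict_bac(back, record, ca=ca) == ba.predict_bac(
            female_model, record, ca=ca)


def test_truncated_document_rejected(female_model):
    doc = ba.serialize_model(female_model)
    with pytest.raises(ModelSchemaError):
        ba.deserialize_model(doc[: len(doc) // 2])
    bad = json.loads(doc)
    bad["schema_version"] = 99
    with pytest.raises(ModelSchemaError, match="version"):
        ba.deserialize_model(json.dumps(bad))
    del bad["schema_version"]
    with pytest.raises(ModelSchemaError):
        ba.deserialize_model(json.dumps(bad))
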