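"""Dichotomization, IRLS logistic fitting, and association diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from ponvkit.assoc_glm import (
    CLINICAL_COVARIATES,
    associate_activity,
    associate_marker,
    bonferroni,
    confounding_scan,
    dichotomize,
    encode_genotype,
    fit_logistic,
    vif,
)
from ponvkit.cohort_synth import LocusSpec, generate_genotypes
from ponvkit.defaults import default_covariate_specs
from ponvkit.cohort_synth import generate_covariates


# ---------------------------------------------------------------------------
# Dichotomization and encodings
# ---------------------------------------------------------------------------

def _raw_row(**overrides):
    row = {
        "sex": "F",
        "age_years": 49,
        "smoker": 1,
        "cannabis_user": 0,
        "ponv_history": 0,
        "surgery_type": "orthopedic",
        "volatile": 1,
        "opioid_mg": 25.0,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def test_dichotomization_rules():
    coded = dichotomize(_raw_row())
    assert coded.loc[0, "Age"] == 1          # 49 < 50
    assert coded.loc[0, "Gender"] == 1       # female
    assert coded.loc[0, "Smoking"] == 0      # active smoker
    assert coded.loc[0, "HighOpioid"] == 1   # 25 mg > 19 mg


def test_opioid_median_boundary_inclusive():
    assert dichotomize(_raw_row(opioid_mg=19.0)).loc[0, "HighOpioid"] == 0
    assert dichotomize(_raw_row(opioid_mg=19.01)).loc[0, "HighOpioid"] == 1


def test_age_boundary_at_fifty():
    assert dichotomize(_raw_row(age_years=50)).loc[0, "Age"] == 0


def test_missing_raw_field_flags_row_incomplete():
    coded = dichotomize(_raw_row(age_years=np.nan))
    assert coded.loc[0, "complete_record"] == 0
    assert math.isnan(coded.loc[0, "Age"])


@pytest.mark.parametrize(
    "encoding,expected",
    [("additive", [0, 1, 2]), ("dominant", [0, 1, 1]), ("recessive", [0, 0, 1])],
)
def test_genotype_encodings(encoding, expected):
    dosage = pd.Series([0.0, 1.0, 2.0, np.nan])
    enc = encode_genotype(dosage, encoding)
    assert enc.iloc[:3].tolist() == [float(v) for v in expected]
    assert math.isnan(enc.iloc[3])


# ---------------------------------------------------------------------------
# IRLS against closed forms and statsmodels
# ---------------------------------------------------------------------------

def _two_by_two_frame(a, b, c, d):
    """a = y1x1, b = y0x1, c = y1x0, d = y0x0."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1] * (a + b) + [0] * (c + d)
    return pd.DataFrame({"y": y, "x": x})


@pytest.mark.parametrize("cells", [(10, 20, 30, 40), (25, 13, 40, 7), (50, 50, 50, 50), (5, 9, 2, 11)])
def test_irls_matches_2x2_closed_form(cells):
    a, b, c, d = cells
    fit = fit_logistic(_two_by_two_frame(a, b, c, d), "y", ["x"])
    beta_oracle = math.log(a * d / (b * c))
    se_oracle = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert fit.coef("x") == pytest.approx(beta_oracle, abs=1e-6)
    assert fit.se[fit.columns.index("x")] == pytest.approx(se_oracle, abs=1e-6)
    assert fit.coef("Intercept") == pytest.approx(math.log(c / d), abs=1e-6)
    assert fit.converged


def test_irls_matches_statsmodels_on_random_design():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    n = 400
    X = pd.DataFrame(
        {
            "x1": rng.integers(0, 2, n),
            "x2": rng.normal(size=n),
            "x3": rng.integers(0, 3, n),
        }
    )
    eta = -0.4 + 0.8 * X["x1"] - 0.5 * X["x2"] + 0.3 * X["x3"]
    X["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    ours = fit_logistic(X, "y", ["x1", "x2", "x3"])
    ref = sm.Logit(X["y"], sm.add_constant(X[["x1", "x2", "x3"]])).fit(disp=0)
    np.testing.assert_allclose(ours.beta, ref.params.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(ours.se, ref.bse.to_numpy(), atol=1e-5)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_null_data_gives_small_coefficients():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"y": rng.integers(0, 2, 10_000), "x": rng.integers(0, 2, 10_000)})
    fit = fit_logistic(df, "y", ["x"])
    assert abs(fit.coef("x")) < 0.1


def test_separation_is_flagged_not_silent():
    df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0] * 20 + [1] * 20})
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic(df, "y", ["x"])
    assert fit.separated and not fit.converged


def test_rank_deficiency_names_aliased_column():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"y": rng.integers(0, 2, 100), "x": rng.integers(0, 2, 100)})
    df["x_dup"] = df["x"]
    with pytest.raises(np.linalg.LinAlgError, match="x_dup|x"):
        fit_logistic(df, "y", ["x", "x_dup"])


def test_additive_fit_symmetric_under_homozygote_label_swap():
    rng = np.random.default_rng(8)
    n = 2000
    d = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.31, 0.49, 0.20])
    eta = -0.5 + 0.4 * d
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"y": y, "g": d, "g_swapped": 2.0 - d})
    f1 = fit_logistic(df, "y", ["g"])
    f2 = fit_logistic(df, "y", ["g_swapped"])
    assert f1.coef("g") == pytest.approx(-f2.coef("g_swapped"), abs=1e-8)
    assert f1.se[1] == pytest.approx(f2.se[1], abs=1e-8)


# ---------------------------------------------------------------------------
# Marker / activity association
# ---------------------------------------------------------------------------

def _cohort_with_marker(n, seed, beta_marker=0.0, maf=0.3):
    from ponvkit.cohort_synth import OutcomeModelSpec, generate_outcomes
    from ponvkit.defaults import default_outcome_model

    specs = default_covariate_specs()
    cov = generate_covariates(specs, n, seed=seed)
    gm, truth = generate_genotypes([LocusSpec("rsM", maf)], n, seed=seed + 7_000_000)
    cov.index = gm.calls.index
    truth["dosage"].index = gm.calls.index
    base = default_outcome_model()
    model = OutcomeModelSpec(
        intercept=base.intercept,
        covariate_betas=base.covariate_betas,
        marker_betas={"rsM": beta_marker},
    )
    df = generate_outcomes(cov, gm, model, seed=seed + 13_000_000, dosage=truth["dosage"])
    return df, gm


def test_marker_test_type_i_error_near_nominal():
    """Size of the covariate-adjusted Wald marker test under a null marker."""
    reps = 400
    hits = 0
    for rep in range(reps):
        df, gm = _cohort_with_marker(601, seed=rep, beta_marker=0.0)
        res = associate_marker("rsM", "ponv_occurrence", df, gm)
        hits += res.p < 0.05
    assert 0.03 <= hits / reps <= 0.07


def test_monomorphic_marker_is_rejected():
    df, gm = _cohort_with_marker(200, seed=1)
    calls = gm.calls.copy()
    calls["rsM"] = "A/A"
    from ponvkit.genotype_qc import GenotypeMatrix

    mono = GenotypeMatrix(calls, gm.variants)
    with pytest.raises(ValueError, match="monomorphic"):
        associate_marker("rsM", "ponv_occurrence", df, mono)


def test_encoding_matching_truth_attains_highest_likelihood():
    """A recessive generating effect is best described by the recessive fit."""
    rng = np.random.default_rng(9)
    n = 20_000
    d = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.36, 0.48, 0.16])
    eta = -0.8 + 1.0 * (d == 2)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"y": y})
    lls = {}
    for enc in ("additive", "dominant", "recessive"):
        df[enc] = encode_genotype(pd.Series(d), enc).to_numpy()
        lls[enc] = fit_logistic(df, "y", [enc]).loglik
    assert max(lls, key=lls.get) == "recessive"


def test_constant_activity_score_is_aliased():
    df, _ = _cohort_with_marker(300, seed=2)
    df["score"] = 1.5
    with pytest.raises(np.linalg.LinAlgError, match="constant|aliased"):
        associate_activity("score", "ponv_occurrence", df)


def test_activity_slope_invariant_under_score_shift():
    df, _ = _cohort_with_marker(2000, seed=3)
    rng = np.random.default_rng(10)
    df["score"] = rng.choice([0.0, 1.0, 2.0, 3.0, 4.0], size=len(df))
    r1 = associate_activity("score", "ponv_occurrence", df)
    df["score"] = df["score"] + 1.0
    r2 = associate_activity("score", "ponv_occurrence", df)
    assert r1.beta == pytest.approx(r2.beta, abs=1e-7)
    assert r1.fit.coef("Intercept") != pytest.approx(r2.fit.coef("Intercept"), abs=1e-3)


# ---------------------------------------------------------------------------
# Bonferroni, VIF, confounding
# ---------------------------------------------------------------------------

def test_bonferroni_threshold_for_27_markers():
    thr, flags = bonferroni([0.005, 0.001], m=27)
    assert thr == pytest.approx(0.05 / 27)
    assert round(thr, 3) == 0.002
    assert flags.tolist() == [False, True]


def test_bonferroni_single_test():
    thr, _ = bonferroni([0.04], m=1)
    assert thr == 0.05


def test_vif_orthogonal_design_is_one():
    df = pd.DataFrame({"a": [0, 0, 1, 1] * 10, "b": [0, 1, 0, 1] * 10})
    v = vif(df, ["a", "b"])
    assert np.allclose(v, 1.0)


def test_vif_duplicated_column_reports_aliased():
    df = pd.DataFrame({"a": [0, 1, 0, 1, 1], "b": [0, 1, 0, 1, 1]})
    v = vif(df, ["a", "b"])
    assert np.isinf(v).all()


def test_default_cohort_vif_below_study_bound(default_cohort):
    v = vif(default_cohort.cohort_table, CLINICAL_COVARIATES)
    assert (v < 1.2).all()


def test_confounding_scan_null_marker_unflagged():
    df, gm = _cohort_with_marker(2000, seed=4)
    report = confounding_scan(["rsM"], "ponv_occurrence", df, gm)
    assert not report["flagged"].any()
    assert (report["relative_change"].abs() < 0.05).all()


def test_confounding_scan_flags_planted_collinear_marker():
    df, gm = _cohort_with_marker(2000, seed=5)
    rng = np.random.default_rng(11)
    # marker strongly collinear with Gender: carrier status tracks Gender
    calls = gm.calls.copy()
    noisy = (df["Gender"].to_numpy() == 1) ^ (rng.random(len(df)) < 0.05)
    calls["rsM"] = np.where(noisy, "A/G", "A/A")
    from ponvkit.genotype_qc import GenotypeMatrix

    planted = GenotypeMatrix(calls, gm.variants)
    report = confounding_scan(["rsM"], "ponv_occurrence", df, planted)
    gender_row = report[report["covariate"] == "Gender"].iloc[0]
    assert abs(gender_row["relative_change"]) > 0.10
    assert gender_row["flagged"]


def test_confounding_flag_threshold_is_strictly_greater_than():
    """A change exactly at the threshold stays unflagged (strict inequality)."""
    df, gm = _cohort_with_marker(1500, seed=6)
    report = confounding_scan(["rsM"], "ponv_occurrence", df, gm)
    row = report.iloc[report["relative_change"].abs().idxmax()]
    at_threshold = confounding_scan(
        ["rsM"], "ponv_occurrence", df, gm, change_threshold=abs(row["relative_change"])
    )
    match = at_threshold[
        (at_threshold["covariate"] == row["covariate"]) & (at_threshold["marker"] == "rsM")
    ].iloc[0]
    assert not match["flagged"]
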