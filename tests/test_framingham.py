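"""Clinical risk equations and three-level categorisation."""

import math

import numpy as np
import pandas as pd
import pytest

from riskstrat import categorize_clinical, frs_cad, frs_htn, frs_t2d

MGDL = 38.67

# Independently hard-coded coefficients of the sex-specific continuous
# Framingham general-CVD function (10-year horizon), used as a manual
# oracle against the data-file-driven implementation.
WOMEN = dict(ln_age=2.32888, ln_tc=1.20904, ln_hdl=-0.70833,
             ln_sbp_untreated=2.76157, ln_sbp_treated=2.82263,
             smoker=0.52873, diabetes=0.69154, s0=0.95012, mean=26.1931)
MEN = dict(ln_age=3.06117, ln_tc=1.12370, ln_hdl=-0.93263,
           ln_sbp_untreated=1.93303, ln_sbp_treated=1.99881,
           smoker=0.65451, diabetes=0.57367, s0=0.88936, mean=23.9802)


def _manual_cad(age, sex, tc, hdl, sbp, treated, smoker):
    b = WOMEN if sex == "female" else MEN
    lp = (b["ln_age"] * math.log(age)
          + b["ln_tc"] * math.log(tc * MGDL)
          + b["ln_hdl"] * math.log(hdl * MGDL)
          + (b["ln_sbp_treated"] if treated else b["ln_sbp_untreated"]) * math.log(sbp)
          + b["smoker"] * smoker)
    return 1.0 - b["s0"] ** math.exp(lp - b["mean"])


def _profile_frame(rows):
    defaults = {
        "age": 55.0, "sex": "female", "sbp": 125.0, "dbp": 78.0,
        "total_chol": 5.5, "ldl": 3.4, "hdl": 1.4, "triglycerides": 1.5,
        "hscrp": 1.5, "fasting_glucose": 5.0, "hba1c_pct": 5.3,
        "bmi": 26.0, "waist": 85.0, "smoking": "never_or_quit_gt1y",
        "bp_treatment": 0, "family_history_cad": 0, "family_history_t2d": 0,
        "family_history_htn": 0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def test_cad_matches_independent_hand_computation():
    rows = [
        {"age": 56, "sex": "female", "total_chol": 5.71, "hdl": 1.47, "sbp": 138},
        {"age": 56, "sex": "male", "total_chol": 5.71, "hdl": 1.47, "sbp": 138},
        {"age": 45, "sex": "male", "total_chol": 7.0, "hdl": 0.9, "sbp": 160,
         "smoking": "current"},
        {"age": 70, "sex": "female", "total_chol": 4.2, "hdl": 1.8, "sbp": 118,
         "bp_treatment": 1},
        {"age": 38, "sex": "male", "total_chol": 5.0, "hdl": 1.2, "sbp": 131},
    ]
    df = _profile_frame(rows)
    got = frs_cad(df)
    for i, r in enumerate(rows):
        expected = _manual_cad(
            r["age"], r["sex"], r["total_chol"], r["hdl"], r["sbp"],
            r.get("bp_treatment", 0), r.get("smoking") == "current")
        assert got[i] == pytest.approx(expected, abs=1e-10)


def test_cad_reference_cell_returns_baseline_risk():
    """A profile whose linear predictor equals the score's population mean
    must return exactly 1 - baseline survival."""
    b = WOMEN
    others = (b["ln_age"] * math.log(56.0)
              + b["ln_tc"] * math.log(5.71 * MGDL)
              + b["ln_hdl"] * math.log(1.47 * MGDL))
    sbp = math.exp((b["mean"] - others) / b["ln_sbp_untreated"])
    df = _profile_frame([{"age": 56.0, "total_chol": 5.71, "hdl": 1.47,
                          "sbp": sbp}])
    assert frs_cad(df)[0] == pytest.approx(1.0 - b["s0"], abs=1e-10)


def test_cad_smoking_strictly_increases_risk():
    df = _profile_frame([{}, {"smoking": "current"}])
    risk = frs_cad(df)
    assert risk[1] > risk[0]


def test_cad_age_outside_validity_range_warns_and_clamps():
    df = _profile_frame([{"age": 29.0}])
    with pytest.warns(UserWarning, match="clamped"):
        risk = frs_cad(df)
    assert risk[0] == frs_cad(_profile_frame([{"age": 30.0}]))[0]


def test_t2d_matches_inline_logistic_evaluation():
    """Dual implementation: the score must equal an inline evaluation of
    the shipped coefficient file to 1e-10."""
    from scipy.special import expit
    rows = [{}, {"fasting_glucose": 6.0}, {"bmi": 33.0, "sex": "male"},
            {"hdl": 0.8, "triglycerides": 3.0, "family_history_t2d": 1},
            {"age": 70.0, "sbp": 134.0, "dbp": 86.0}]
    df = _profile_frame(rows)
    got = frs_t2d(df)
    for i in range(len(df)):
        r = df.iloc[i]
        lp = (-3.66 + 0.04 * (r.age - 56.3) + 0.2 * (r.sex == "male")
              + 0.55 * (r.family_history_t2d >= 1) + 0.09 * (r.bmi - 26.8)
              - 0.9 * (r.hdl - 1.47) + 0.25 * (r.triglycerides - 1.68)
              + 0.9 * (r.fasting_glucose - 5.0)
              + 0.3 * ((r.sbp >= 130) or (r.dbp >= 85) or r.bp_treatment == 1))
        assert got[i] == pytest.approx(float(expit(lp)), abs=1e-10)


def test_t2d_glucose_strictly_increases_risk():
    df = _profile_frame([{"fasting_glucose": 4.8}, {"fasting_glucose": 5.8}])
    risk = frs_t2d(df)
    assert risk[1] > risk[0]


def test_htn_matches_inline_logistic_evaluation():
    from scipy.special import expit
    rows = [{}, {"sbp": 135.0, "dbp": 85.0}, {"age": 40.0, "bmi": 22.0},
            {"smoking": "current", "family_history_htn": 2},
            {"sex": "male", "sbp": 128.0}]
    df = _profile_frame(rows)
    got = frs_htn(df)
    for i in range(len(df)):
        r = df.iloc[i]
        lp = (-1.4 + 0.06 * (r.age - 56.3) + 0.2 * (r.sex == "male")
              + 0.5 * (r.family_history_htn >= 1) + 0.05 * (r.bmi - 26.8)
              + 0.08 * (r.sbp - 130) + 0.06 * (r.dbp - 80)
              + 0.3 * (r.smoking == "current"))
        assert got[i] == pytest.approx(float(expit(lp)), abs=1e-10)


def test_htn_sbp_strictly_increases_risk():
    df = _profile_frame([{"sbp": 112.0}, {"sbp": 126.0}])
    risk = frs_htn(df)
    assert risk[1] > risk[0]


def test_probabilities_lie_in_unit_interval(rng):
    n = 100
    df = pd.DataFrame({
        "age": rng.uniform(30, 74, n),
        "sex": rng.choice(["female", "male"], n),
        "sbp": rng.uniform(90, 139, n), "dbp": rng.uniform(60, 89, n),
        "total_chol": rng.uniform(3, 9, n), "ldl": rng.uniform(1, 6, n),
        "hdl": rng.uniform(0.5, 2.5, n), "triglycerides": rng.uniform(0.4, 5, n),
        "hscrp": rng.uniform(0.1, 10, n),
        "fasting_glucose": rng.uniform(3.5, 7, n),
        "hba1c_pct": rng.uniform(4, 7, n), "bmi": rng.uniform(18, 45, n),
        "waist": rng.uniform(60, 130, n),
        "smoking": rng.choice(["never_or_quit_gt1y", "current"], n),
        "bp_treatment": rng.integers(0, 2, n),
        "family_history_cad": rng.integers(0, 3, n),
        "family_history_t2d": rng.integers(0, 3, n),
        "family_history_htn": rng.integers(0, 3, n),
    })
    for fn in (frs_cad, frs_t2d, frs_htn):
        p = fn(df)
        assert np.all((p >= 0) & (p <= 1))


# --- categorisation ---------------------------------------------------------

def test_t2d_cutpoints_with_closed_intermediate_interval():
    p = np.array([0.02, 0.03, 0.05, 0.08, 0.09])
    cats = categorize_clinical(p, "t2d")
    assert list(cats) == ["low", "intermediate", "intermediate",
                          "intermediate", "high"]


def test_htn_cutpoints():
    p = np.array([0.04, 0.05, 0.10, 0.11])
    cats = categorize_clinical(p, "htn")
    assert list(cats) == ["low", "intermediate", "intermediate", "high"]


def test_cad_tertiles_split_nine_distinct_probabilities_evenly():
    p = np.linspace(0.01, 0.09, 9)
    sex = np.array(["female"] * 9)
    cats = categorize_clinical(p, "cad", sex=sex)
    assert list(cats) == ["low"] * 3 + ["intermediate"] * 3 + ["high"] * 3


def test_cad_tertiles_are_sex_specific(rng):
    p = np.concatenate([rng.uniform(0, 0.1, 30), rng.uniform(0.2, 0.5, 30)])
    sex = np.array(["female"] * 30 + ["male"] * 30)
    cats = categorize_clinical(p, "cad", sex=sex)
    # each sex gets its own tertile split despite disjoint risk ranges
    for s in ("female", "male"):
        sub = cats[sex == s]
        assert sorted(set(sub)) == ["high", "intermediate", "low"]
        assert all((sub == lab).sum() == 10 for lab in set(sub))


def test_category_is_monotone_in_probability(rng):
    p = rng.uniform(0, 1, 200)
    order = {"low": 0, "intermediate": 1, "high": 2}
    for cond in ("t2d", "htn"):
        cats = np.vectorize(order.get)(categorize_clinical(p, cond))
        idx = np.argsort(p)
        assert np.all(np.diff(cats[idx]) >= 0)


def test_empty_cohort_cannot_be_categorised():
    with pytest.raises(ValueError, match="empty"):
        categorize_clinical(np.array([]), "cad")
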