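"""Framingham-style clinical risk scores and three-level risk categories.

Three absolute-risk equations are evaluated from vendored, swappable
coefficient files (delimited text under ``riskstrat/data``):

* CAD — the sex-specific continuous Framingham general cardiovascular
  function (D'Agostino et al. 2008), 10-year horizon;
* T2D — an 8-year incident-diabetes logistic equation with the predictors
  of the Framingham Offspring simple clinical model (synthetic stand-in
  coefficients; see the data file header);
* HTN — an incident-hypertension logistic equation with the predictors of
  the Framingham hypertension score (synthetic stand-in coefficients).

Probabilities are then mapped to {low, intermediate, high}: CAD by
sex-specific cohort tertiles; T2D by <3% / 3–8% / >8%; HTN by
<5% / 5–10% / >10%.  Cutpoint boundaries belong to the intermediate
category; tertile ties are broken toward the lower tertile via midranks.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .cohort import CONDITIONS

#: mmol/L -> mg/dL conversion for cholesterol.
CHOL_MGDL_PER_MMOL = 38.67

#: Absolute-risk category cutpoints (low < lo; lo..hi intermediate; > hi high).
CATEGORY_CUTPOINTS = {"t2d": (0.03, 0.08), "htn": (0.05, 0.10)}

CAD_AGE_RANGE = (30.0, 74.0)


def _data_file(name: str) -> pd.DataFrame:
    path = resources.files("riskstrat.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_cad_coefficients(name: str = "frs_cad_general_cvd_2008.tsv") -> dict:
    table = _data_file(name)
    out: dict[str, dict[str, float]] = {}
    for sex, grp in table.groupby("sex"):
        out[sex] = dict(zip(grp["term"], grp["value"]))
    return out


def load_logistic_coefficients(name: str) -> pd.DataFrame:
    """Coefficient file with columns term, coefficient, center."""
    return _data_file(name).set_index("term")


def _clamp_age(age: np.ndarray, clamp: bool) -> np.ndarray:
    lo, hi = CAD_AGE_RANGE
    out = np.asarray(age, dtype=float)
    if ((out < lo) | (out > hi)).any():
        if not clamp:
            raise ValueError(f"age outside the score's validity range {CAD_AGE_RANGE}")
        warnings.warn(
            f"ages outside {CAD_AGE_RANGE} clamped for Framingham evaluation",
            stacklevel=3)
        out = np.clip(out, lo, hi)
    return out


def frs_cad(df: pd.DataFrame, diabetes: np.ndarray | None = None,
            clamp_age: bool = True,
            coefficients: dict | None = None) -> np.ndarray:
    """10-year coronary/cardiovascular risk, sex-specific continuous form.

    Expects columns age, sex, total_chol (mmol/L), hdl (mmol/L), sbp,
    bp_treatment, smoking.  ``diabetes`` defaults to ``diagnosed_t2d``
    when present, else zero (analysis cohorts exclude diabetics).
    """
    coefs = coefficients or load_cad_coefficients()
    age = _clamp_age(df["age"].to_numpy(), clamp_age)
    tc = np.log(df["total_chol"].to_numpy(dtype=float) * CHOL_MGDL_PER_MMOL)
    hdl = np.log(df["hdl"].to_numpy(dtype=float) * CHOL_MGDL_PER_MMOL)
    sbp = np.log(df["sbp"].to_numpy(dtype=float))
    treated = df["bp_treatment"].to_numpy(dtype=float) if "bp_treatment" in df else 0.0
    smoker = (df["smoking"] == "current").to_numpy(dtype=float)
    if diabetes is None:
        diabetes = (df["diagnosed_t2d"].to_numpy(dtype=float)
                    if "diagnosed_t2d" in df else np.zeros(len(df)))
    risk = np.empty(len(df))
    for sex in ("female", "male"):
        b = coefs[sex]
        m = (df["sex"] == sex).to_numpy()
        lp = (b["ln_age"] * np.log(age)
              + b["ln_total_chol"] * tc
              + b["ln_hdl"] * hdl
              + np.where(np.asarray(treated) > 0,
                         b["ln_sbp_treated"], b["ln_sbp_untreated"]) * sbp
              + b["smoker"] * smoker
              + b["diabetes"] * np.asarray(diabetes, dtype=float))
        risk[m] = 1.0 - b["baseline_survival"] ** np.exp(lp[m] - b["mean_lp"])
    return np.clip(risk, 0.0, 1.0)


def _logistic_score(features: pd.DataFrame, coefs: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(features), float(coefs.loc["intercept", "coefficient"]))
    for term, row in coefs.iterrows():
        if term == "intercept":
            continue
        lp += row["coefficient"] * (features[term].to_numpy(dtype=float) - row["center"])
    return expit(lp)


def frs_t2d(df: pd.DataFrame,
            coefficients: pd.DataFrame | None = None) -> np.ndarray:
    """8-year incident type-2-diabetes probability.

    Predictors: age, sex, parental diabetes history, BMI, HDL,
    triglycerides, fasting glucose, and an elevated-blood-pressure
    indicator (>=130/85 mmHg or on treatment).
    """
    coefs = coefficients if coefficients is not None \
        else load_logistic_coefficients("frs_t2d_synthetic_logistic.tsv")
    features = pd.DataFrame({
        "age": df["age"],
        "male": (df["sex"] == "male").astype(float),
        "parental_history": (df["family_history_t2d"] >= 1).astype(float),
        "bmi": df["bmi"],
        "hdl": df["hdl"],
        "triglycerides": df["triglycerides"],
        "fasting_glucose": df["fasting_glucose"],
        "elevated_bp": ((df["sbp"] >= 130) | (df["dbp"] >= 85)
                        | (df.get("bp_treatment", 0) == 1)).astype(float),
    })
    return _logistic_score(features, coefs)


def frs_htn(df: pd.DataFrame,
            coefficients: pd.DataFrame | None = None) -> np.ndarray:
    """Near-term incident-hypertension probability.

    Predictors: age, sex, SBP, DBP, BMI, current smoking, parental
    hypertension.  Intended for cohorts already restricted to
    normotensive/prehypertensive participants.
    """
    coefs = coefficients if coefficients is not None \
        else load_logistic_coefficients("frs_htn_synthetic_logistic.tsv")
    features = pd.DataFrame({
        "age": df["age"],
        "male": (df["sex"] == "male").astype(float),
        "parental_history": (df["family_history_htn"] >= 1).astype(float),
        "bmi": df["bmi"],
        "sbp": df["sbp"],
        "dbp": df["dbp"],
        "smoker": (df["smoking"] == "current").astype(float),
    })
    return _logistic_score(features, coefs)


FRS_FUNCTIONS = {"cad": frs_cad, "t2d": frs_t2d, "htn": frs_htn}


def categorize_clinical(
    probabilities: np.ndarray,
    condition: str,
    sex: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Map absolute-risk probabilities to {low, intermediate, high}.

    CAD uses tertiles of the supplied cohort distribution, computed
    within sex (pass ``sex``); ties are assigned by average rank, broken
    toward the lower tertile.  T2D and HTN use fixed cutpoints with
    closed intermediate intervals.
    """
    p = np.asarray(probabilities, dtype=float)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition}")
    if p.size == 0:
        raise ValueError("empty cohort: cannot categorise")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if condition in CATEGORY_CUTPOINTS:
        lo, hi = CATEGORY_CUTPOINTS[condition]
        return np.where(p < lo, "low", np.where(p > hi, "high", "intermediate"))
    # CAD: sex-specific cohort tertiles
    out = np.empty(p.size, dtype=object)
    if sex is None:
        groups = [np.arange(p.size)]
    else:
        sex = np.asarray(sex)
        groups = [np.flatnonzero(sex == s) for s in np.unique(sex)]
    for idx in groups:
        if idx.size == 0:
            continue
        ranks = rankdata(p[idx], method="average")
        n = idx.size
        cat = np.where(ranks <= n / 3, "low",
                       np.where(ranks <= 2 * n / 3, "intermediate", "high"))
        out[idx] = cat
    return out.astype(str)
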