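"""Decision-rules classifiers producing a four-level risk stratum.

Each condition's engine maps a participant profile, their clinical
(Framingham) risk category and their genetic risk group to an ordinal
stratum NOT_ELEVATED < ELEVATED < HIGH < CLINICAL:

* CLINICAL — a baseline clinical threshold is crossed (BP >= 140/90 for
  CAD/HTN, fasting glucose > 7.0 mmol/L for T2D); such participants are
  referred to care, not advised lifestyle intervention.
* HIGH — any decisive rule fires (e.g. total cholesterol above 8 mmol/L
  for CAD; fasting glucose above 6.1 mmol/L for T2D; high-normal blood
  pressure for HTN; or combinations of elevated markers with high
  clinical or genetic risk).
* NOT_ELEVATED — every relevant biomarker within its reference range,
  PRS below the eighth decile, and (per condition) negative family
  history or low clinical risk.
* ELEVATED — everything else (at least one marker out of range but no
  decisive rule).

Only the HIGH stratum maps to "advised lifestyle intervention" — the
dichotomy under which sensitivity, specificity and reclassification are
computed downstream.

Every satisfied clause is recorded per participant in ``fired_rules`` so
a decision can be replayed and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import IntEnum

import numpy as np
import pandas as pd


class RiskStratum(IntEnum):
    NOT_ELEVATED = 0
    ELEVATED = 1
    HIGH = 2
    CLINICAL = 3


@dataclass
class CadRules:
    total_chol_high: float = 8.0       # mmol/L, strict
    sbp_high: float = 180.0            # mmHg, strict
    ldl_high: float = 4.9              # mmol/L, strict
    tg_out_of_range: float = 1.7       # mmol/L, strict (conventional cutpoint)
    crp_out_of_range: float = 3.0      # mg/L, strict (conventional cutpoint)
    # reference ranges for the low-risk arm ("no biomarkers out of range")
    normal_total_chol: float = 5.0
    normal_ldl: float = 3.0
    normal_hdl_min: float = 1.0
    normal_sbp: float = 130.0


@dataclass
class T2dRules:
    hba1c_high: float = 6.5            # % NGSP, strict
    glucose_high: float = 6.1          # mmol/L, strict
    hba1c_elevated: tuple[float, float] = (5.5, 6.4)     # closed interval
    glucose_elevated: tuple[float, float] = (5.6, 6.1)   # closed interval
    overweight_bmi: float = 25.0       # kg/m2, inclusive
    age_over: float = 45.0             # years, strict
    hdl_low: float = 0.9               # mmol/L, strict
    tg_high: float = 2.8               # mmol/L, strict
    # one conjunctive rule (clinical high AND glucose unregulated AND PRS
    # high); False reads the clause list as three separate rules
    conjunctive_high_rule: bool = True
    # reference ranges for the low-risk arm
    normal_glucose: float = 5.6
    normal_hba1c: float = 5.5
    normal_bmi: float = 25.0
    normal_hdl_min: float = 1.0
    normal_tg: float = 1.7


@dataclass
class HtnRules:
    sbp_high_normal: tuple[float, float] = (130.0, 139.0)  # closed
    dbp_high_normal: tuple[float, float] = (80.0, 89.0)    # closed
    # reference ranges for the low-risk arm
    normal_sbp: float = 130.0
    normal_dbp: float = 80.0
    normal_bmi: float = 25.0


@dataclass
class ClinicalThresholds:
    sbp: float = 140.0        # inclusive
    dbp: float = 90.0         # inclusive
    glucose: float = 7.0      # strict


@dataclass
class RuleConfig:
    cad: CadRules = field(default_factory=CadRules)
    t2d: T2dRules = field(default_factory=T2dRules)
    htn: HtnRules = field(default_factory=HtnRules)
    clinical: ClinicalThresholds = field(default_factory=ClinicalThresholds)
    prs_low_decile_below: int = 8     # low arm requires decile < 8

    def to_dict(self) -> dict:
        return asdict(self)


def _collect(strata: np.ndarray, fired: list[list[str]],
             index) -> pd.DataFrame:
    return pd.DataFrame({
        "stratum": pd.Categorical.from_codes(
            strata, categories=[s.name for s in RiskStratum], ordered=True),
        "fired_rules": ["; ".join(f) for f in fired],
    }, index=index)


def _apply(clauses: list[tuple[np.ndarray, str]], n: int) -> tuple[np.ndarray, list[list[str]]]:
    fired: list[list[str]] = [[] for _ in range(n)]
    agg = np.zeros(n, dtype=bool)
    for mask, name in clauses:
        mask = np.asarray(mask, dtype=bool)
        agg |= mask
        for i in np.flatnonzero(mask):
            fired[i].append(name)
    return agg, fired


def stratify_cad(
    df: pd.DataFrame,
    clinical_category: np.ndarray,
    prs_decile: np.ndarray,
    config: RuleConfig | None = None,
) -> pd.DataFrame:
    """CAD decision rules.

    HIGH if total cholesterol > 8 mmol/L, SBP > 180 mmHg, LDL > 4.9
    mmol/L, or (triglycerides and/or hs-CRP out of range) together with a
    high clinical or genetic risk.  NOT_ELEVATED if no CAD biomarker is
    out of range, the PRS decile is below 8 and family history is
    negative.  Otherwise ELEVATED.
    """
    cfg = config or RuleConfig()
    r = cfg.cad
    n = len(df)
    clin = np.asarray(clinical_category)
    dec = np.asarray(prs_decile)
    prs_high = dec == 10

    clinical_mask = (df["sbp"].to_numpy() >= cfg.clinical.sbp) \
        | (df["dbp"].to_numpy() >= cfg.clinical.dbp)
    tg_oor = df["triglycerides"].to_numpy() > r.tg_out_of_range
    crp_oor = df["hscrp"].to_numpy() > r.crp_out_of_range
    high_clauses = [
        (df["total_chol"].to_numpy() > r.total_chol_high, "tc>8"),
        (df["sbp"].to_numpy() > r.sbp_high, "sbp>180"),
        (df["ldl"].to_numpy() > r.ldl_high, "ldl>4.9"),
        ((tg_oor | crp_oor) & ((clin == "high") | prs_high),
         "tg/crp out of range + high clinical or genetic risk"),
    ]
    high, fired = _apply(high_clauses, n)

    out_of_range = (
        (df["total_chol"].to_numpy() > r.normal_total_chol)
        | (df["ldl"].to_numpy() > r.normal_ldl)
        | (df["hdl"].to_numpy() < r.normal_hdl_min)
        | tg_oor | crp_oor
        | (df["sbp"].to_numpy() >= r.normal_sbp)
    )
    low = (~out_of_range) & (dec < cfg.prs_low_decile_below) \
        & (df["family_history_cad"].to_numpy() == 0)

    strata = np.where(clinical_mask, RiskStratum.CLINICAL,
                      np.where(high, RiskStratum.HIGH,
                               np.where(low, RiskStratum.NOT_ELEVATED,
                                        RiskStratum.ELEVATED))).astype(int)
    for i in np.flatnonzero(clinical_mask):
        fired[i].insert(0, "clinical threshold BP>=140/90")
    for i in np.flatnonzero(strata == RiskStratum.ELEVATED):
        fired[i].append("at least one risk factor elevated")
    return _collect(strata, fired, df.index)


def stratify_t2d(
    df: pd.DataFrame,
    clinical_category: np.ndarray,
    prs_decile: np.ndarray,
    config: RuleConfig | None = None,
) -> pd.DataFrame:
    """Type-2-diabetes decision rules.

    The "glucose unregulated" state in the conjunctive high-risk clause
    is the elevated glycaemic state itself (HbA1c 5.5–6.4 % or fasting
    glucose 5.6–6.1 mmol/L).
    """
    cfg = config or RuleConfig()
    r = cfg.t2d
    n = len(df)
    clin = np.asarray(clinical_category)
    dec = np.asarray(prs_decile)
    prs_high = dec == 10

    glucose = df["fasting_glucose"].to_numpy()
    hba1c = df["hba1c_pct"].to_numpy()
    clinical_mask = glucose > cfg.clinical.glucose
    glyc_elev = ((hba1c >= r.hba1c_elevated[0]) & (hba1c <= r.hba1c_elevated[1])) \
        | ((glucose >= r.glucose_elevated[0]) & (glucose <= r.glucose_elevated[1]))

    high_clauses = [
        ((hba1c > r.hba1c_high) & (glucose < r.glucose_high),
         "hba1c>6.5 with glucose<6.1"),
        (glucose > r.glucose_high, "glucose>6.1"),
        (glyc_elev & (df["bmi"].to_numpy() >= r.overweight_bmi),
         "elevated glycaemia + overweight"),
        ((clin == "intermediate") & (df["age"].to_numpy() > r.age_over)
         & (df["hdl"].to_numpy() < r.hdl_low)
         & (df["triglycerides"].to_numpy() > r.tg_high),
         "elevated clinical risk + age>45 + low HDL + high TG"),
    ]
    if r.conjunctive_high_rule:
        high_clauses.append((
            (clin == "high") & glyc_elev & prs_high,
            "high clinical risk + unregulated glucose + high genetic risk"))
    else:
        high_clauses += [((clin == "high"), "high clinical risk"),
                         (glyc_elev, "unregulated glucose"),
                         (prs_high, "high genetic risk")]
    high, fired = _apply(high_clauses, n)

    out_of_range = (
        (glucose >= r.normal_glucose)
        | (hba1c >= r.normal_hba1c)
        | (df["bmi"].to_numpy() >= r.normal_bmi)
        | (df["hdl"].to_numpy() < r.normal_hdl_min)
        | (df["triglycerides"].to_numpy() > r.normal_tg)
    )
    low = (~out_of_range) & (dec < cfg.prs_low_decile_below) & (clin == "low")

    strata = np.where(clinical_mask, RiskStratum.CLINICAL,
                      np.where(high, RiskStratum.HIGH,
                               np.where(low, RiskStratum.NOT_ELEVATED,
                                        RiskStratum.ELEVATED))).astype(int)
    for i in np.flatnonzero(clinical_mask):
        fired[i].insert(0, "clinical threshold glucose>7.0")
    for i in np.flatnonzero(strata == RiskStratum.ELEVATED):
        fired[i].append("at least one risk factor elevated")
    return _collect(strata, fired, df.index)


def stratify_htn(
    df: pd.DataFrame,
    clinical_category: np.ndarray,
    prs_decile: np.ndarray,
    config: RuleConfig | None = None,
) -> pd.DataFrame:
    """Hypertension decision rules.

    HIGH on high-normal blood pressure (SBP 130–139 and/or DBP 80–89,
    closed intervals), a high clinical risk, or an intermediate clinical
    risk combined with a high PRS.
    """
    cfg = config or RuleConfig()
    r = cfg.htn
    n = len(df)
    clin = np.asarray(clinical_category)
    dec = np.asarray(prs_decile)
    sbp = df["sbp"].to_numpy()
    dbp = df["dbp"].to_numpy()

    clinical_mask = (sbp >= cfg.clinical.sbp) | (dbp >= cfg.clinical.dbp)
    high_clauses = [
        ((sbp >= r.sbp_high_normal[0]) & (sbp <= r.sbp_high_normal[1]),
         "sbp high-normal 130-139"),
        ((dbp >= r.dbp_high_normal[0]) & (dbp <= r.dbp_high_normal[1]),
         "dbp high-normal 80-89"),
        (clin == "high", "high clinical risk"),
        ((clin == "intermediate") & (dec == 10),
         "elevated clinical risk + high genetic risk"),
    ]
    high, fired = _apply(high_clauses, n)

    out_of_range = (sbp >= r.normal_sbp) | (dbp >= r.normal_dbp) \
        | (df["bmi"].to_numpy() >= r.normal_bmi)
    low = (~out_of_range) & (dec < cfg.prs_low_decile_below) & (clin == "low")

    strata = np.where(clinical_mask, RiskStratum.CLINICAL,
                      np.where(high, RiskStratum.HIGH,
                               np.where(low, RiskStratum.NOT_ELEVATED,
                                        RiskStratum.ELEVATED))).astype(int)
    for i in np.flatnonzero(clinical_mask):
        fired[i].insert(0, "clinical threshold BP>=140/90")
    for i in np.flatnonzero(strata == RiskStratum.ELEVATED):
        fired[i].append("at least one risk factor elevated")
    return _collect(strata, fired, df.index)


STRATIFY_FUNCTIONS = {"cad": stratify_cad, "t2d": stratify_t2d, "htn": stratify_htn}


def advised_intervention(strata: pd.Series | np.ndarray) -> np.ndarray:
    """True iff the stratum is HIGH.

    CLINICAL participants are referred to medical care rather than
    advised lifestyle intervention, so they are negatives under this
    dichotomy, as are ELEVATED and NOT_ELEVATED.
    """
    values = strata
    if isinstance(strata, pd.Series) and isinstance(strata.dtype, pd.CategoricalDtype):
        values = strata.astype(str).to_numpy()
    values = np.asarray(values)
    if values.dtype.kind in "iu":
        return values == int(RiskStratum.HIGH)
    return values == RiskStratum.HIGH.name
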