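"""Baseline exclusion rules forming the per-condition analysis cohorts.

Participants are excluded from a condition's analysis cohort if, at
baseline, they (i) already carry a physician diagnosis of that condition,
(ii) cross a clinical threshold — at least grade-1 hypertension
(SBP >= 140 mmHg and/or DBP >= 90 mmHg) or fasting glucose above
7.0 mmol/L, (iii) have significantly impaired kidney function (default
reading: eGFR < 60 mL/min/1.73m2 or ACR > 3 mg/mmol — KDIGO-style
thresholds, configurable because the exact guideline function used for the
original cohort is not numerically specified), or (iv) are missing any
mandatory variable.  By default the clinical-threshold exclusions apply to
all three cohorts; this is switchable per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, Cohort

DEFAULT_MANDATORY = [
    "age", "sex", "sbp", "dbp", "total_chol", "ldl", "hdl", "triglycerides",
    "hscrp", "fasting_glucose", "hba1c_pct", "bmi", "waist", "smoking",
    "bp_treatment", "egfr", "acr",
] + [f"family_history_{c}" for c in CONDITIONS]

REASON_DIAGNOSED = "baseline diagnosis"
REASON_BP = "blood pressure >= 140/90"
REASON_GLUCOSE = "fasting glucose > 7.0 mmol/L"
REASON_KIDNEY = "impaired kidney function"


@dataclass
class EligibilityConfig:
    sbp_limit: float = 140.0
    dbp_limit: float = 90.0
    glucose_limit: float = 7.0
    egfr_min: float = 60.0
    acr_max: float = 3.0
    #: apply BP/glucose threshold exclusions to every cohort, not just the
    #: matching condition's
    thresholds_global: bool = True
    mandatory_fields: list[str] = field(default_factory=lambda: list(DEFAULT_MANDATORY))

    def validate(self) -> None:
        for key in ("sbp_limit", "dbp_limit", "glucose_limit", "egfr_min", "acr_max"):
            if getattr(self, key) is None:
                raise ValueError(f"eligibility threshold missing: {key}")


@dataclass
class ExclusionReport:
    """Per-participant exclusion outcome and per-condition cohort sizes.

    ``table`` has one row per (participant, condition) with ``kept`` and a
    semicolon-joined ordered reason list (empty iff kept); ``counts`` maps
    condition -> {reason -> first-matching-rule count}, ``sizes`` maps
    condition -> kept cohort size.
    """

    table: pd.DataFrame
    counts: dict[str, dict[str, int]]
    sizes: dict[str, int]
    n_input: int


def _reasons_for(df: pd.DataFrame, condition: str, cfg: EligibilityConfig
                 ) -> list[list[str]]:
    n = len(df)
    reasons: list[list[str]] = [[] for _ in range(n)]

    def col(name: str) -> pd.Series:
        return df[name] if name in df.columns else pd.Series(np.nan, index=df.index)

    checks: list[tuple[np.ndarray, str]] = []
    diag = col(f"diagnosed_{condition}")
    checks.append(((diag == 1).to_numpy(), REASON_DIAGNOSED))
    if cfg.thresholds_global or condition == "htn":
        bp = (col("sbp") >= cfg.sbp_limit) | (col("dbp") >= cfg.dbp_limit)
        checks.append((bp.fillna(False).to_numpy(), REASON_BP))
    if cfg.thresholds_global or condition == "t2d":
        glu = col("fasting_glucose") > cfg.glucose_limit
        checks.append((glu.fillna(False).to_numpy(), REASON_GLUCOSE))
    kidney = (col("egfr") < cfg.egfr_min) | (col("acr") > cfg.acr_max)
    checks.append((kidney.fillna(False).to_numpy(), REASON_KIDNEY))
    for name in cfg.mandatory_fields:
        missing = (~col(name).notna()).to_numpy() if name in df.columns \
            else np.ones(n, dtype=bool)
        checks.append((missing, f"missing: {name}"))

    for mask, message in checks:
        for i in np.flatnonzero(mask):
            reasons[i].append(message)
    return reasons


def apply_baseline_exclusions(
    cohort: Cohort,
    config: EligibilityConfig | None = None,
) -> tuple[dict[str, Cohort], ExclusionReport]:
    """Apply baseline exclusions, returning per-condition analysis cohorts.

    Every removal is logged; the summary counts attribute each excluded
    participant to their first matching rule.  Kept + excluded equals the
    input size for every condition, and re-applying the exclusions to a
    kept cohort removes no one.
    """
    cfg = config or EligibilityConfig()
    cfg.validate()
    df = cohort.data
    kept_cohorts: dict[str, Cohort] = {}
    rows = []
    counts: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for condition in CONDITIONS:
        reasons = _reasons_for(df, condition, cfg)
        kept_mask = np.array([len(r) == 0 for r in reasons])
        kept_cohorts[condition] = cohort.subset(
            kept_mask, note=f"baseline exclusions applied for {condition}")
        first_rule: dict[str, int] = {}
        for r in reasons:
            if r:
                first_rule[r[0]] = first_rule.get(r[0], 0) + 1
        counts[condition] = first_rule
        sizes[condition] = int(kept_mask.sum())
        rows.append(pd.DataFrame({
            "id": df["id"], "condition": condition, "kept": kept_mask,
            "reasons": ["; ".join(r) for r in reasons],
        }))
    report = ExclusionReport(
        table=pd.concat(rows, ignore_index=True),
        counts=counts, sizes=sizes, n_input=len(df),
    )
    return kept_cohorts, report
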