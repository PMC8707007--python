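"""Independent brute-force evaluation of the decision-rule clause logic.

Transcribed directly from the verbal rule definitions, clause by clause
and per participant, with no shared code with the vectorised engines.
Used by the truth-table equivalence tests.
"""


def oracle_cad(p: dict, clinical: str, decile: int) -> str:
    if p["sbp"] >= 140 or p["dbp"] >= 90:
        return "CLINICAL"
    tg_oor = p["triglycerides"] > 1.7
    crp_oor = p["hscrp"] > 3.0
    high = (
        p["total_chol"] > 8.0
        or p["sbp"] > 180.0
        or p["ldl"] > 4.9
        or ((tg_oor or crp_oor) and (clinical == "high" or decile == 10))
    )
    if high:
        return "HIGH"
    in_range = (
        p["total_chol"] <= 5.0 and p["ldl"] <= 3.0 and p["hdl"] >= 1.0
        and not tg_oor and not crp_oor and p["sbp"] < 130.0
    )
    if in_range and decile < 8 and p["family_history_cad"] == 0:
        return "NOT_ELEVATED"
    return "ELEVATED"


def oracle_t2d(p: dict, clinical: str, decile: int) -> str:
    if p["fasting_glucose"] > 7.0:
        return "CLINICAL"
    glyc_elev = (5.5 <= p["hba1c_pct"] <= 6.4) or (5.6 <= p["fasting_glucose"] <= 6.1)
    high = (
        (p["hba1c_pct"] > 6.5 and p["fasting_glucose"] < 6.1)
        or p["fasting_glucose"] > 6.1
        or (glyc_elev and p["bmi"] >= 25.0)
        or (clinical == "high" and glyc_elev and decile == 10)
        or (clinical == "intermediate" and p["age"] > 45
            and p["hdl"] < 0.9 and p["triglycerides"] > 2.8)
    )
    if high:
        return "HIGH"
    in_range = (
        p["fasting_glucose"] < 5.6 and p["hba1c_pct"] < 5.5 and p["bmi"] < 25.0
        and p["hdl"] >= 1.0 and p["triglycerides"] <= 1.7
    )
    if in_range and decile < 8 and clinical == "low":
        return "NOT_ELEVATED"
    return "ELEVATED"


def oracle_htn(p: dict, clinical: str, decile: int) -> str:
    if p["sbp"] >= 140 or p["dbp"] >= 90:
        return "CLINICAL"
    high = (
        130.0 <= p["sbp"] <= 139.0
        or 80.0 <= p["dbp"] <= 89.0
        or clinical == "high"
        or (clinical == "intermediate" and decile == 10)
    )
    if high:
        return "HIGH"
    in_range = p["sbp"] < 130.0 and p["dbp"] < 80.0 and p["bmi"] < 25.0
    if in_range and decile < 8 and clinical == "low":
        return "NOT_ELEVATED"
    return "ELEVATED"
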