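"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline can run and be verified without access-controlled data:

* baseline biomarker marginals matching a large middle-aged population
  cohort (mean SBP 138 mmHg, mean total cholesterol 5.71 mmol/L, ...),
  with a latent "metabolic" factor correlating BMI, triglycerides,
  glucose, HbA1c and SBP;
* an additive genetic liability: per-variant binomial(2, allele freq)
  dosages, normally distributed weights, true PRS = dosage x weight;
* per-condition incident events from an exponential proportional-hazards
  model with a linear predictor over centred risk factors plus the
  standardised PRS, administratively censored at the follow-up horizon
  (default 8.8 years).

Everything is deterministic given the config seed.  A truth record keeps
each participant's true PRS and per-condition linear predictor for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, Cohort, ngsp_from_ifcc

#: Baseline marginals (mean, sd) used as generator defaults.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (56.3, 7.59),
    "sbp": (138.0, 19.0),
    "dbp": (82.0, 10.0),
    "total_chol": (5.71, 1.1),
    "ldl": (3.58, 0.84),
    "hdl": (1.47, 0.38),
    "triglycerides": (1.68, 0.97),
    "hscrp": (2.17, 3.8),
    "fasting_glucose": (5.0, 1.0),
    "hba1c_ifcc": (35.2, 5.3),
    "bmi": (26.8, 4.35),
    "waist": (88.7, 12.8),
    "acr": (2.4, 8.3),
    "egfr": (95.0, 13.0),
}

#: One-parent / two-parent family-history prevalences per condition.
DEFAULT_FAMILY_HISTORY = {
    "cad": (0.418, 0.0007),
    "t2d": (0.168, 0.0001),
    "htn": (0.427, 0.0008),
}

#: Loadings of the latent metabolic factor on correlated biomarkers.
DEFAULT_METABOLIC_LOADINGS = {
    "bmi": 0.55,
    "triglycerides": 0.40,
    "fasting_glucose": 0.45,
    "hba1c_ifcc": 0.40,
    "sbp": 0.30,
}


def _default_condition_params() -> dict[str, "ConditionParams"]:
    ln = math.log
    return {
        "cad": ConditionParams(
            baseline_hazard=0.0010,
            log_hr_per_sd_prs=ln(1.8),
            log_hr_coefficients={
                "age": 0.05, "male": 0.60, "sbp": 0.015, "total_chol": 0.25,
                "hdl": -0.60, "smoking_current": 0.60,
            },
        ),
        "t2d": ConditionParams(
            baseline_hazard=0.0015,
            log_hr_per_sd_prs=ln(1.6),
            log_hr_coefficients={
                "age": 0.03, "bmi": 0.12, "fasting_glucose": 0.80,
                "family_history": 0.50,
            },
        ),
        "htn": ConditionParams(
            baseline_hazard=0.0060,
            log_hr_per_sd_prs=ln(1.35),
            log_hr_coefficients={
                "age": 0.04, "sbp": 0.03, "dbp": 0.02, "bmi": 0.05,
                "family_history": 0.30,
            },
        ),
    }


@dataclass
class ConditionParams:
    """Event-generation parameters for one condition.

    ``baseline_hazard`` is the constant hazard (events/person-year) for a
    participant at the covariate centres with average genetic risk;
    ``log_hr_coefficients`` maps risk-factor names to per-unit log hazard
    ratios (covariates are centred at the marginal means before use).
    """

    baseline_hazard: float
    log_hr_per_sd_prs: float = 0.0
    log_hr_coefficients: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_participants: int = 40_000
    n_variants: int = 1_000
    seed: int = 0
    horizon_years: float = 8.8
    female_fraction: float = 0.512
    smoking_probs: tuple[float, float] = (0.056, 0.003)  # current, quit<1y
    bp_treatment_fraction: float = 0.02
    diagnosed_fraction: float = 0.02
    missing_rate: float = 0.0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    metabolic_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METABOLIC_LOADINGS))
    family_history: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_HISTORY))
    conditions: dict[str, ConditionParams] = field(
        default_factory=_default_condition_params)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        for name, params in self.conditions.items():
            if params.baseline_hazard <= 0:
                raise ValueError(f"{name}: baseline hazard must be positive")


def generate_weights(n_variants: int, seed: int) -> pd.DataFrame:
    """Variant weight table: id, effect allele, weight, frequency, info.

    Weights are mean-zero normal (per-allele log-odds scale); imputation
    quality ("info") is uniform on [0.3, 1] so the default 0.4 filter has
    something to remove.  Deterministic given ``seed``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "variant_id": [f"var{i:06d}" for i in range(n_variants)],
        "effect_allele": rng.choice(list("ACGT"), size=n_variants),
        "weight": rng.normal(0.0, 0.05, size=n_variants),
        "allele_freq": rng.uniform(0.05, 0.95, size=n_variants),
        "info": rng.uniform(0.3, 1.0, size=n_variants),
    })


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _loaded_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                   factor: np.ndarray, loading: float) -> np.ndarray:
    """Normal with the given marginal moments, partly driven by ``factor``."""
    eps = rng.normal(size=n)
    return mean + sd * (loading * factor + math.sqrt(1.0 - loading ** 2) * eps)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[Cohort, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, dosage matrix, weight table, truth record).

    The truth record stores, per participant, the true PRS (raw and
    standardised) and each condition's linear predictor and hazard, so
    recovery tests can compare estimates against the generating values.
    """
    config.validate()
    n = config.n_participants
    root = np.random.default_rng(config.seed)
    # independent child streams so adding a stage never perturbs another
    seeds = root.integers(0, 2**31 - 1, size=8)
    weights = generate_weights(config.n_variants, int(seeds[0]))
    lo, hi = config.allele_freq_range
    # regenerate frequencies within the configured range (weight table
    # defaults to (0.05, 0.95))
    if (lo, hi) != (0.05, 0.95):
        rng_f = np.random.default_rng(int(seeds[1]))
        weights["allele_freq"] = rng_f.uniform(lo, hi, size=config.n_variants)

    rng_g = np.random.default_rng(int(seeds[2]))
    dosage = rng_g.binomial(
        2, weights["allele_freq"].to_numpy()[None, :], size=(n, config.n_variants)
    ).astype(np.int8)
    ids = [f"P{i:06d}" for i in range(n)]
    dosages = pd.DataFrame(dosage, index=ids, columns=weights["variant_id"])
    true_prs = dosage @ weights["weight"].to_numpy()
    prs_sd = true_prs.std(ddof=0)
    prs_z = (true_prs - true_prs.mean()) / (prs_sd if prs_sd > 0 else 1.0)

    rng_b = np.random.default_rng(int(seeds[3]))
    m = config.marginals
    load = config.metabolic_loadings
    z_met = rng_b.normal(size=n)

    def draw(col: str) -> np.ndarray:
        return _loaded_normal(rng_b, n, *m[col], z_met, load.get(col, 0.0))

    age = np.clip(draw("age"), 37.0, 73.0)
    female = rng_b.random(n) < config.female_fraction
    sbp = draw("sbp")
    zsbp = (sbp - m["sbp"][0]) / m["sbp"][1]
    dbp = m["dbp"][0] + m["dbp"][1] * (0.45 * zsbp + math.sqrt(1 - 0.45**2) * rng_b.normal(size=n))
    dbp = np.minimum(dbp, sbp - 5.0)  # enforce sbp > dbp (rare tail)
    tc = np.clip(draw("total_chol"), 1.5, None)
    ztc = (tc - m["total_chol"][0]) / m["total_chol"][1]
    ldl = np.clip(
        m["ldl"][0] + m["ldl"][1] * (0.8 * ztc + 0.6 * rng_b.normal(size=n)), 0.3, None)
    hdl = np.clip(draw("hdl"), 0.4, None)
    mu, sig = _lognormal_params(*m["triglycerides"])
    tg = np.exp(mu + sig * (load["triglycerides"] * z_met
                            + math.sqrt(1 - load["triglycerides"]**2) * rng_b.normal(size=n)))
    mu, sig = _lognormal_params(*m["hscrp"])
    crp = np.exp(mu + sig * rng_b.normal(size=n))
    glucose = np.clip(draw("fasting_glucose"), 2.5, None)
    hba1c_pct = np.clip(ngsp_from_ifcc(draw("hba1c_ifcc")), 3.5, 19.0)
    bmi = np.clip(draw("bmi"), 15.0, None)
    zbmi = (bmi - m["bmi"][0]) / m["bmi"][1]
    waist = np.clip(
        m["waist"][0] + m["waist"][1] * (0.7 * zbmi + math.sqrt(1 - 0.49) * rng_b.normal(size=n)),
        50.0, None)
    mu, sig = _lognormal_params(*m["acr"])
    acr = np.exp(mu + sig * rng_b.normal(size=n))
    egfr = np.clip(rng_b.normal(*m["egfr"], size=n), 25.0, 150.0)

    u = rng_b.random(n)
    p_cur, p_quit = config.smoking_probs
    smoking = np.where(u < p_cur, "current",
                       np.where(u < p_cur + p_quit, "quit_lt1y", "never_or_quit_gt1y"))
    bp_treatment = (rng_b.random(n) < config.bp_treatment_fraction).astype(int)

    df = pd.DataFrame({
        "id": ids, "age": age, "sex": np.where(female, "female", "male"),
        "sbp": sbp, "dbp": dbp, "total_chol": tc, "ldl": ldl, "hdl": hdl,
        "triglycerides": tg, "hscrp": crp, "fasting_glucose": glucose,
        "hba1c_pct": hba1c_pct, "bmi": bmi, "waist": waist,
        "smoking": smoking, "bp_treatment": bp_treatment,
        "egfr": egfr, "acr": acr,
    })
    rng_h = np.random.default_rng(int(seeds[4]))
    for c in CONDITIONS:
        p1, p2 = config.family_history[c]
        u = rng_h.random(n)
        df[f"family_history_{c}"] = np.where(u < p2, 2, np.where(u < p2 + p1, 1, 0))
        df[f"diagnosed_{c}"] = (rng_h.random(n) < config.diagnosed_fraction).astype(int)
    for j in range(1, 5):
        df[f"pc{j}"] = rng_h.normal(size=n)
    df["genotyping_array"] = (rng_h.random(n) < 0.5).astype(int)

    # --- incident events: exponential proportional hazards ---------------
    centres = {k: v[0] for k, v in m.items()}
    rng_e = np.random.default_rng(int(seeds[5]))
    truth = pd.DataFrame({"id": ids, "true_prs": true_prs, "prs_z": prs_z})
    for c, params in config.conditions.items():
        lp = np.zeros(n)
        for name, beta in params.log_hr_coefficients.items():
            if name == "male":
                x = (~female).astype(float)
            elif name == "smoking_current":
                x = (smoking == "current").astype(float)
            elif name == "family_history":
                x = df[f"family_history_{c}"].to_numpy(dtype=float)
            elif name in df.columns:
                x = df[name].to_numpy(dtype=float) - centres.get(name, 0.0)
            else:
                raise KeyError(f"unknown risk factor '{name}' for condition '{c}'")
            lp += beta * x
        lp += params.log_hr_per_sd_prs * prs_z
        hazard = params.baseline_hazard * np.exp(lp)
        t_event = rng_e.exponential(1.0 / hazard)
        event = t_event < config.horizon_years
        time = np.where(event, t_event, config.horizon_years)
        df[f"event_{c}"] = event.astype(int)
        df[f"time_{c}"] = np.maximum(time, 1e-6)
        truth[f"lp_{c}"] = lp
        truth[f"hazard_{c}"] = hazard

    if config.missing_rate > 0:
        rng_m = np.random.default_rng(int(seeds[6]))
        missable = ["total_chol", "ldl", "hdl", "triglycerides", "hscrp",
                    "fasting_glucose", "hba1c_pct", "bmi", "waist", "egfr", "acr"]
        for col in missable:
            mask = rng_m.random(n) < config.missing_rate
            df.loc[mask, col] = np.nan

    cohort = Cohort(df)
    cohort.note(f"simulated n={n}, variants={config.n_variants}, seed={config.seed}")
    return cohort, dosages, weights, truth
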