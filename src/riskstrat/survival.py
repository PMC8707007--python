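"""Proportional-hazards estimation of stratum effects and incidence curves.

Hazard ratios between risk strata and a reference stratum come from a Cox
partial-likelihood fit (Efron tie handling, Wald intervals) delegated to
lifelines; absolute risks are Kaplan–Meier 1 - S(t) at the follow-up
horizon.  A stratum with zero events is reported with a degenerate-CI
flag instead of a silently exploding estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

import statsmodels.api as sm


@dataclass
class StratumEstimate:
    label: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    absolute_risk: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StratumSurvival:
    reference: str
    reference_n: int
    reference_events: int
    reference_absolute_risk: float
    strata: list[StratumEstimate] = field(default_factory=list)
    person_years: float = 0.0
    horizon: float = np.nan

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "reference_n": self.reference_n,
            "reference_events": self.reference_events,
            "reference_absolute_risk": self.reference_absolute_risk,
            "person_years": self.person_years,
            "horizon": self.horizon,
            "strata": [s.to_dict() for s in self.strata],
        }


def _km_risk(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    if times.size == 0:
        return float("nan")
    km = KaplanMeierFitter()
    km.fit(times, events)
    return float(1.0 - km.predict(horizon))


def fit_cox_strata(
    times: np.ndarray,
    events: np.ndarray,
    strata: np.ndarray,
    reference: str,
    horizon: float | None = None,
) -> StratumSurvival:
    """Cox PH fit of stratum indicators against the reference stratum.

    Also reports per-stratum Kaplan–Meier absolute risk at ``horizon``
    (default: the largest observed time) and total person-years.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(strata).astype(str)
    labels = [lab for lab in pd.unique(s) if lab != str(reference)]
    if str(reference) not in s:
        raise ValueError(f"reference stratum '{reference}' not present")
    if not labels:
        raise ValueError("need at least two strata")
    horizon = float(horizon if horizon is not None else t.max())

    df = pd.DataFrame({"time": t, "event": e})
    cols = []
    for lab in labels:
        col = f"stratum_{lab}"
        df[col] = (s == lab).astype(float)
        cols.append(col)
    zero_event = {lab: int(e[s == lab].sum()) == 0 for lab in labels}
    ref_events = int(e[s == str(reference)].sum())

    cph = CoxPHFitter()
    fitted = False
    for penalizer in (0.0, 0.1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=penalizer)
                cph.fit(df, duration_col="time", event_col="event")
            fitted = True
            penalized = penalizer > 0
            break
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
    if not fitted:
        raise RuntimeError("Cox model failed to converge")

    summary = cph.summary
    out = StratumSurvival(
        reference=str(reference),
        reference_n=int((s == str(reference)).sum()),
        reference_events=ref_events,
        reference_absolute_risk=_km_risk(t[s == str(reference)],
                                         e[s == str(reference)], horizon),
        person_years=float(t.sum()),
        horizon=horizon,
    )
    for lab in labels:
        row = summary.loc[f"stratum_{lab}"]
        mask = s == lab
        with np.errstate(over="ignore"):
            hr, lo, hi = (float(np.exp(row["coef"])),
                          float(np.exp(row["coef lower 95%"])),
                          float(np.exp(row["coef upper 95%"])))
        out.strata.append(StratumEstimate(
            label=lab,
            hazard_ratio=hr,
            ci_low=lo,
            ci_high=hi,
            p_value=float(row["p"]),
            n=int(mask.sum()),
            n_events=int(e[mask].sum()),
            absolute_risk=_km_risk(t[mask], e[mask], horizon),
            degenerate=zero_event[lab] or ref_events == 0 or penalized,
        ))
    return out


CONTRASTS = ("top_vs_rest", "top_vs_1to7", "8and9_vs_1to7")


def prs_decile_hrs(
    times: np.ndarray,
    events: np.ndarray,
    deciles: np.ndarray,
    contrast: str = "top_vs_rest",
    covariates: pd.DataFrame | None = None,
    mode: str = "cox",
) -> dict:
    """HR (or OR) for a genetic-risk decile contrast.

    Contrasts: decile 10 vs all others, decile 10 vs deciles 1–7, or
    deciles 8–9 vs deciles 1–7.  ``mode="cox"`` fits a proportional-
    hazards model; ``mode="logistic"`` fits a logistic model and returns
    an odds ratio (for parity with analyses that report decile effects
    from logistic regressions).  Optional covariates are entered
    additively.
    """
    d = np.asarray(deciles, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if contrast == "top_vs_rest":
        keep = np.ones(d.size, dtype=bool)
        exposed = d == 10
    elif contrast == "top_vs_1to7":
        keep = (d == 10) | (d <= 7)
        exposed = d == 10
    elif contrast == "8and9_vs_1to7":
        keep = d <= 9
        exposed = (d == 8) | (d == 9)
    else:
        raise ValueError(f"unknown contrast: {contrast} (choose from {CONTRASTS})")
    if exposed[keep].sum() == 0 or (~exposed[keep]).sum() == 0:
        raise ValueError("empty contrast group")

    X = pd.DataFrame({"exposed": exposed[keep].astype(float)})
    if covariates is not None:
        X = pd.concat([X, covariates.loc[keep].reset_index(drop=True).astype(float)],
                      axis=1)
    if mode == "cox":
        df = X.copy()
        df["time"] = t[keep]
        df["event"] = e[keep]
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        row = cph.summary.loc["exposed"]
        return {
            "contrast": contrast, "measure": "hazard_ratio",
            "estimate": float(np.exp(row["coef"])),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
            "p_value": float(row["p"]),
            "n_exposed": int(exposed[keep].sum()),
            "n_events": int(e[keep].sum()),
        }
    if mode == "logistic":
        Xc = sm.add_constant(X)
        fit = sm.Logit(e[keep], Xc).fit(disp=0)
        coef = fit.params["exposed"]
        lo, hi = fit.conf_int().loc["exposed"]
        return {
            "contrast": contrast, "measure": "odds_ratio",
            "estimate": float(np.exp(coef)),
            "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
            "p_value": float(fit.pvalues["exposed"]),
            "n_exposed": int(exposed[keep].sum()),
            "n_events": int(e[keep].sum()),
        }
    raise ValueError(f"unknown mode: {mode}")


def cumulative_incidence(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> pd.DataFrame:
    """Kaplan–Meier cumulative incidence 1 - S(t) per group.

    Long-format frame with columns group, time, cum_incidence, ci_low,
    ci_high (pointwise 95%), suitable for plotting or TSV export.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups).astype(str)
    frames = []
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask])
        surv = km.survival_function_
        ci = km.confidence_interval_survival_function_
        frames.append(pd.DataFrame({
            "group": label,
            "time": surv.index.to_numpy(dtype=float),
            "cum_incidence": 1.0 - surv.iloc[:, 0].to_numpy(),
            "ci_low": 1.0 - ci.iloc[:, 1].to_numpy(),
            "ci_high": 1.0 - ci.iloc[:, 0].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
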