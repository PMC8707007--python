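"""Discrimination and reclassification statistics.

Implements the evaluation layer at the advised-intervention dichotomy:
confusion counts, sensitivity/specificity/PPV/NPV with binomial or
bootstrap confidence intervals, AUROC by the midrank Mann–Whitney
statistic with a stratified bootstrap CI, DeLong's paired test for
correlated AUROC differences, and the two-category Net Reclassification
Index with its asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint


@dataclass
class MetricEstimate:
    point: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    se: float = np.nan
    p_value: float = np.nan
    method: str = ""

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_at_high(advised: np.ndarray, events: np.ndarray) -> ConfusionCounts:
    """Cross-tabulate advised-intervention status against incident events."""
    a = np.asarray(advised, dtype=bool)
    e = np.asarray(events, dtype=bool)
    if a.shape != e.shape:
        raise ValueError("advised and events must be aligned")
    return ConfusionCounts(
        tp=int(np.sum(a & e)), fn=int(np.sum(~a & e)),
        fp=int(np.sum(a & ~e)), tn=int(np.sum(~a & ~e)),
    )


def _binomial_estimate(k: int, n: int, alpha: float, name: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(point=np.nan, method=f"{name}: undefined (zero denominator)")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    p = k / n
    return MetricEstimate(point=p, ci_low=float(lo), ci_high=float(hi),
                          se=float(np.sqrt(p * (1 - p) / n)), method="wilson")


def sens_spec(counts: ConfusionCounts, alpha: float = 0.05,
              floor_zero_cells: bool = False) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with Wilson CIs.

    A metric with a zero denominator is returned flagged as undefined
    (NaN point, explanatory method label) rather than silently NaN.
    ``floor_zero_cells`` replaces empty cells with 1 before computing the
    ratios — the convention sometimes used in published count tables so
    that ratio statistics stay finite for zero-event strata.
    """
    if floor_zero_cells:
        counts = ConfusionCounts(tp=max(counts.tp, 1), fn=max(counts.fn, 1),
                                 fp=max(counts.fp, 1), tn=max(counts.tn, 1))
    return {
        "sensitivity": _binomial_estimate(counts.tp, counts.tp + counts.fn, alpha, "sensitivity"),
        "specificity": _binomial_estimate(counts.tn, counts.tn + counts.fp, alpha, "specificity"),
        "ppv": _binomial_estimate(counts.tp, counts.tp + counts.fp, alpha, "ppv"),
        "npv": _binomial_estimate(counts.tn, counts.tn + counts.fn, alpha, "npv"),
    }


def _auc_midrank(scores: np.ndarray, events: np.ndarray) -> float:
    ranks = rankdata(scores, method="average")
    m = int(events.sum())
    n = events.size - m
    return (ranks[events].sum() - m * (m + 1) / 2.0) / (m * n)


def auroc(
    scores: np.ndarray,
    events: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MetricEstimate:
    """AUROC via the midrank Mann–Whitney statistic with bootstrap CI.

    Midranks make the statistic well defined for discrete ordinal
    predictors (such as three-level rule strata).  The CI is the
    percentile interval over ``n_boot`` resamples stratified by event
    status, so no resample is single-class; deterministic given ``seed``.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=bool)
    if s.shape != e.shape:
        raise ValueError("scores and events must be aligned")
    if e.all() or not e.any():
        raise ValueError("need at least one event and one non-event")
    point = _auc_midrank(s, e)
    if n_boot <= 0:
        return MetricEstimate(point=point, method="mann-whitney midrank")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(e)
    ctrl_idx = np.flatnonzero(~e)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=case_idx.size, replace=True)
        ni = rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)
        idx = np.concatenate([ci, ni])
        ev = np.zeros(idx.size, dtype=bool)
        ev[:ci.size] = True
        stats[b] = _auc_midrank(s[idx], ev)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return MetricEstimate(point=point, ci_low=float(lo), ci_high=float(hi),
                          se=float(stats.std(ddof=1)),
                          method=f"mann-whitney midrank, {n_boot} stratified bootstrap")


def _delong_components(scores: np.ndarray, events: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-observation structural components V10 (cases), V01."""
    cases = scores[events]
    ctrls = scores[~events]
    m, n = cases.size, ctrls.size
    tx = rankdata(np.concatenate([cases, ctrls]), method="average")
    tz_cases = rankdata(cases, method="average")
    tz_ctrls = rankdata(ctrls, method="average")
    auc = (tx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tx[:m] - tz_cases) / n
    v01 = 1.0 - (tx[m:] - tz_ctrls) / m
    return auc, v10, v01


def delong_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    events: np.ndarray,
) -> MetricEstimate:
    """Paired DeLong test for the difference of two correlated AUROCs.

    Returns the difference AUC(a) - AUC(b) with its DeLong standard
    error, Wald CI and two-sided p-value.  Identical predictors give a
    zero difference with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (a.shape == b.shape == e.shape):
        raise ValueError("both score vectors must align with events")
    if e.all() or not e.any():
        raise ValueError("need at least one event and one non-event")
    auc_a, v10_a, v01_a = _delong_components(a, e)
    auc_b, v10_b, v01_b = _delong_components(b, e)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    diff = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if diff == 0 else np.nan
        return MetricEstimate(point=diff, se=0.0, p_value=p,
                              ci_low=diff, ci_high=diff, method="delong (degenerate)")
    se = float(np.sqrt(var))
    z = diff / se
    p = float(2 * norm.sf(abs(z)))
    return MetricEstimate(point=diff, se=se, p_value=p,
                          ci_low=diff - 1.96 * se, ci_high=diff + 1.96 * se,
                          method="delong")


@dataclass
class ReclassificationTable:
    """Movement counts between two advised/not-advised classifiers.

    "up" = not advised under the old model but advised under the new;
    "down" = the reverse; split by event status.
    """

    up_events: int
    down_events: int
    same_high_events: int
    same_low_events: int
    up_nonevents: int
    down_nonevents: int
    same_high_nonevents: int
    same_low_nonevents: int

    @property
    def n_events(self) -> int:
        return (self.up_events + self.down_events
                + self.same_high_events + self.same_low_events)

    @property
    def n_nonevents(self) -> int:
        return (self.up_nonevents + self.down_nonevents
                + self.same_high_nonevents + self.same_low_nonevents)

    def swap(self) -> "ReclassificationTable":
        """Table with old and new classifiers interchanged."""
        return ReclassificationTable(
            up_events=self.down_events, down_events=self.up_events,
            same_high_events=self.same_high_events, same_low_events=self.same_low_events,
            up_nonevents=self.down_nonevents, down_nonevents=self.up_nonevents,
            same_high_nonevents=self.same_high_nonevents,
            same_low_nonevents=self.same_low_nonevents,
        )

    def to_dict(self) -> dict:
        return {**self.__dict__, "n_events": self.n_events,
                "n_nonevents": self.n_nonevents}


def build_reclassification(
    old_advised: np.ndarray,
    new_advised: np.ndarray,
    events: np.ndarray,
) -> ReclassificationTable:
    """Cross-tabulate movement between two classifiers, split by events."""
    old = np.asarray(old_advised, dtype=bool)
    new = np.asarray(new_advised, dtype=bool)
    e = np.asarray(events, dtype=bool)
    if not (old.shape == new.shape == e.shape):
        raise ValueError("classifier and event vectors must be aligned")

    def cell(o: bool, nw: bool, ev: bool) -> int:
        return int(np.sum((old == o) & (new == nw) & (e == ev)))

    return ReclassificationTable(
        up_events=cell(False, True, True), down_events=cell(True, False, True),
        same_high_events=cell(True, True, True), same_low_events=cell(False, False, True),
        up_nonevents=cell(False, True, False), down_nonevents=cell(True, False, False),
        same_high_nonevents=cell(True, True, False),
        same_low_nonevents=cell(False, False, False),
    )


def nri(table: ReclassificationTable, alpha: float = 0.05) -> MetricEstimate:
    """Two-category Net Reclassification Index, on the percent scale.

    NRI% = 100 x [(up_e - down_e)/n_e - (up_ne - down_ne)/n_ne], with the
    standard asymptotic variance
    var = [p_up_e + p_down_e - (p_up_e - p_down_e)^2]/n_e + (same, nonevents),
    a Wald CI and a two-sided z-test.
    """
    ne, nn = table.n_events, table.n_nonevents
    if ne == 0 or nn == 0:
        raise ValueError("NRI needs both events and non-events")
    pu_e, pd_e = table.up_events / ne, table.down_events / ne
    pu_n, pd_n = table.up_nonevents / nn, table.down_nonevents / nn
    point = (pu_e - pd_e) - (pu_n - pd_n)
    var = (pu_e + pd_e - (pu_e - pd_e) ** 2) / ne \
        + (pu_n + pd_n - (pu_n - pd_n) ** 2) / nn
    se = float(np.sqrt(var))
    z = point / se if se > 0 else 0.0
    p = float(2 * norm.sf(abs(z))) if se > 0 else (1.0 if point == 0 else 0.0)
    crit = norm.ppf(1 - alpha / 2)
    return MetricEstimate(
        point=100 * point, se=100 * se, p_value=p,
        ci_low=100 * (point - crit * se), ci_high=100 * (point + crit * se),
        method="two-category NRI, asymptotic",
    )


def nri_bootstrap(
    old_advised: np.ndarray,
    new_advised: np.ndarray,
    events: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MetricEstimate:
    """Bootstrap cross-check of the asymptotic NRI interval.

    Resamples participants stratified by event status and reports the
    percentile CI of the percent-scale NRI.
    """
    old = np.asarray(old_advised, dtype=bool)
    new = np.asarray(new_advised, dtype=bool)
    e = np.asarray(events, dtype=bool)
    point = nri(build_reclassification(old, new, e)).point
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(e)
    ctrl_idx = np.flatnonzero(~e)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(case_idx, size=case_idx.size, replace=True),
            rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)])
        stats[b] = nri(build_reclassification(old[idx], new[idx], e[idx])).point
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return MetricEstimate(point=point, ci_low=float(lo), ci_high=float(hi),
                          se=float(stats.std(ddof=1)),
                          method=f"two-category NRI, {n_boot} stratified bootstrap")
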