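"""Additive polygenic scoring, QC filtering, adjustment and decile binning.

The score is the plain additive model score_i = sum_j dosage_ij * weight_j
over a pre-computed (LD-corrected) weight table.  Variants with an
imputation-quality (INFO / imputation R^2) score below the configured
threshold — default 0.4, exclusive — are removed before scoring.  Missing
dosages are imputed as twice the effect-allele frequency.

Decile 10 holds the highest scores; the genetic risk groups are
"high" (decile 10), "elevated" (deciles 8–9) and "reference" (1–7).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

GROUP_OF_DECILE = {**{d: "reference" for d in range(1, 8)},
                   8: "elevated", 9: "elevated", 10: "high"}

WEIGHT_COLUMNS = ["variant_id", "effect_allele", "weight", "allele_freq", "info"]


def load_weights(path: str | Path) -> pd.DataFrame:
    """Read a TSV weight table (variant_id, effect_allele, weight, allele_freq, info)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("variant_id", "effect_allele", "weight") if c not in table.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if table["variant_id"].duplicated().any():
        raise ValueError("weight table has duplicate variant ids")
    return table


def filter_variants(weights: pd.DataFrame, min_info: float = 0.4) -> pd.DataFrame:
    """Drop variants whose imputation-quality score is below ``min_info``.

    The removal is exclusive: a variant with info exactly equal to the
    threshold is kept.
    """
    if not 0.0 <= min_info <= 1.0:
        raise ValueError("min_info must lie in [0, 1]")
    if "info" not in weights.columns or min_info == 0.0:
        return weights.copy()
    kept = weights.loc[weights["info"] >= min_info].reset_index(drop=True)
    n_removed = len(weights) - len(kept)
    if n_removed:
        warnings.warn(f"removed {n_removed} variants with info < {min_info}",
                      stacklevel=2)
    return kept


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Additive PRS: per-participant dot product of dosages and weights.

    ``dosages`` is participants x variants with values in [0, 2].  A
    variant present in the weight table but absent from the matrix (or a
    NaN cell) is imputed as 2 x allele_freq; if no allele frequency is
    available the variant is an error, never silently dropped.
    """
    w = weights.set_index("variant_id")
    have = w.index.intersection(dosages.columns)
    absent = w.index.difference(dosages.columns)
    if len(absent):
        freqs = w.loc[absent, "allele_freq"] if "allele_freq" in w.columns \
            else pd.Series(np.nan, index=absent)
        unknown = freqs.index[freqs.isna()].tolist()
        if unknown:
            raise KeyError(
                f"variants absent from dosage matrix with no allele_freq: {unknown[:10]}")
    scores = np.zeros(len(dosages))
    if len(have):
        block = dosages[have].to_numpy(dtype=float)
        if np.isnan(block).any():
            if "allele_freq" not in w.columns or w.loc[have, "allele_freq"].isna().any():
                raise KeyError("NaN dosages present but allele_freq unavailable")
            fill = 2.0 * w.loc[have, "allele_freq"].to_numpy()
            nan_mask = np.isnan(block)
            block[nan_mask] = np.broadcast_to(fill, block.shape)[nan_mask]
        scores += block @ w.loc[have, "weight"].to_numpy()
    if len(absent):
        scores += float((2.0 * w.loc[absent, "allele_freq"] * w.loc[absent, "weight"]).sum())
    return pd.Series(scores, index=dosages.index, name="prs")


def adjust_scores(
    raw: pd.Series | np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    include_prs: bool = True,
    mode: str = "linear_predictor",
) -> tuple[np.ndarray, object]:
    """Covariate adjustment of the PRS via a logistic outcome model.

    Fits logit(P(event)) ~ PRS + covariates (typically genotyping array,
    four principal components, age and sex) and returns the fitted
    per-participant linear predictor as the adjusted score.  With
    ``include_prs=False`` the model is covariates-only (the age-and-sex
    comparison model).  ``mode="residual"`` instead returns the raw score
    residualised on the covariates by least squares.

    Returns (adjusted_scores, fitted_model).
    """
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = covariates.astype(float).copy()
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        # zero-variance covariates are collinear with the intercept
        X = X.drop(columns=constant)
    if mode == "residual":
        Xc = sm.add_constant(X)
        ols = sm.OLS(raw, Xc).fit()
        return raw - ols.fittedvalues, ols
    if include_prs:
        X.insert(0, "prs", raw)
    Xc = sm.add_constant(X)
    model = sm.Logit(y, Xc)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # includes perfect separation
        raise RuntimeError(f"logistic adjustment failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic adjustment did not converge")
    return np.asarray(Xc @ fit.params, dtype=float), fit


def bin_deciles(scores: pd.Series | np.ndarray) -> pd.DataFrame:
    """Assign PRS deciles (1..10, 10 = highest) and genetic risk groups.

    Ranks use the average-rank convention; a tied block lands in the
    decile of its average rank.  The degenerate all-equal input collapses
    to decile 1 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 10:
        raise ValueError("need at least 10 scores to form deciles")
    if np.all(s == s[0]):
        warnings.warn("all scores identical; assigning everyone to decile 1",
                      stacklevel=2)
        deciles = np.ones(n, dtype=int)
    else:
        ranks = rankdata(s, method="average")
        deciles = np.clip(np.ceil(ranks * 10.0 / n).astype(int), 1, 10)
    groups = np.array([GROUP_OF_DECILE[d] for d in deciles])
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.DataFrame({"decile": deciles, "group": groups}, index=index)


def decile_incidence(
    deciles: np.ndarray,
    events: np.ndarray,
    ages: np.ndarray | None = None,
    age_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-decile event fraction, optionally split by baseline-age bin.

    An empty decile is reported with NaN incidence (undefined), never
    zero.  Without ``ages`` the result has one row per decile with
    columns n, n_events, incidence.
    """
    d = np.asarray(deciles)
    e = np.asarray(events, dtype=float)
    if d.shape != e.shape:
        raise ValueError("deciles and events must be aligned")
    rows = []
    for dec in range(1, 11):
        mask = d == dec
        n = int(mask.sum())
        rows.append({
            "decile": dec, "n": n, "n_events": int(e[mask].sum()),
            "incidence": float(e[mask].mean()) if n else np.nan,
        })
    table = pd.DataFrame(rows)
    if ages is None:
        return table
    a = np.asarray(ages, dtype=float)
    bins = age_bins if age_bins is not None else np.arange(35, 80, 5)
    idx = np.digitize(a, bins)
    curves = []
    for dec in range(1, 11):
        for b in np.unique(idx):
            mask = (d == dec) & (idx == b)
            if mask.sum() == 0:
                continue
            curves.append({
                "decile": dec,
                "age_bin_low": float(bins[b - 1]) if b >= 1 and b - 1 < len(bins) else np.nan,
                "n": int(mask.sum()),
                "incidence": float(e[mask].mean()),
            })
    return pd.DataFrame(curves)
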