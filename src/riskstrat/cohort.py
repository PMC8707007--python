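"""Cohort data model and delimited-text I/O.

A cohort is one row per participant: baseline biomarkers, physical
measurements, smoking and family history, plus per-condition follow-up
(incident-event flag and time to event or censoring, in years).  Units are
fixed and never auto-detected: concentrations in mmol/L (hs-CRP in mg/L),
blood pressure in mmHg, HbA1c in NGSP percent.  An IFCC mmol/mol HbA1c
column is accepted on input and converted to percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Health conditions handled throughout the package.
CONDITIONS = ("cad", "t2d", "htn")

SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never_or_quit_gt1y", "quit_lt1y", "current")

# NGSP% = 0.09148 * IFCC(mmol/mol) + 2.152  (standard master-equation inverse)
NGSP_SLOPE = 0.09148
NGSP_INTERCEPT = 2.152

#: Canonical column order for cohort files.
CORE_COLUMNS = [
    "id", "age", "sex", "sbp", "dbp",
    "total_chol", "ldl", "hdl", "triglycerides", "hscrp",
    "fasting_glucose", "hba1c_pct", "bmi", "waist",
    "smoking", "bp_treatment", "egfr", "acr",
]
PER_CONDITION_COLUMNS = (
    [f"family_history_{c}" for c in CONDITIONS]
    + [f"diagnosed_{c}" for c in CONDITIONS]
    + [f"event_{c}" for c in CONDITIONS]
    + [f"time_{c}" for c in CONDITIONS]
)
#: Optional covariates used by the PRS adjustment model.
OPTIONAL_COLUMNS = ["pc1", "pc2", "pc3", "pc4", "genotyping_array"]

CANONICAL_COLUMNS = CORE_COLUMNS + PER_CONDITION_COLUMNS + OPTIONAL_COLUMNS

STRING_COLUMNS = {"id", "sex", "smoking"}
#: Columns that must hold 0/1 when present.
BINARY_COLUMNS = (
    {"bp_treatment", "genotyping_array"}
    | {f"diagnosed_{c}" for c in CONDITIONS}
    | {f"event_{c}" for c in CONDITIONS}
)

#: Mandatory columns for ingestion (everything else may be absent).
MANDATORY_COLUMNS = ("id", "age", "sex")


def ngsp_from_ifcc(ifcc: np.ndarray | float) -> np.ndarray | float:
    """Convert HbA1c from IFCC mmol/mol to NGSP percent."""
    return NGSP_SLOPE * np.asarray(ifcc, dtype=float) + NGSP_INTERCEPT


@dataclass
class Cohort:
    """Validated participant table plus provenance notes.

    ``data`` holds one row per participant with canonical column names;
    ids are unique.  ``provenance`` is an append-only list of free-text
    notes (source file, filters applied).
    """

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise ValueError("cohort table must have an 'id' column")
        if self.data["id"].duplicated().any():
            dupes = self.data.loc[self.data["id"].duplicated(), "id"].tolist()[:5]
            raise ValueError(f"duplicate participant ids: {dupes}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def note(self, message: str) -> None:
        self.provenance.append(message)

    def subset(self, mask: np.ndarray | pd.Series, note: str | None = None) -> "Cohort":
        """New cohort restricted to rows where ``mask`` is true."""
        sub = Cohort(self.data.loc[np.asarray(mask)].reset_index(drop=True),
                     list(self.provenance))
        if note:
            sub.note(note)
        return sub


def _row_violations(df: pd.DataFrame) -> pd.Series:
    """Per-row list of invariant violations (empty list = valid row).

    Checks apply only where values are present; missing cells are left to
    the eligibility stage, mirroring the baseline-exclusion design.
    """
    reasons: list[list[str]] = [[] for _ in range(len(df))]

    def flag(mask: pd.Series, message: str) -> None:
        for i in np.flatnonzero(np.asarray(mask, dtype=bool)):
            reasons[i].append(message)

    def present(col: str) -> pd.Series:
        return df[col].notna() if col in df.columns else pd.Series(False, index=df.index)

    if "age" in df.columns:
        flag(present("age") & (df["age"] <= 0), "age must be positive")
    if "sex" in df.columns:
        flag(present("sex") & ~df["sex"].isin(SEX_LEVELS),
             f"sex must be one of {SEX_LEVELS}")
    if "smoking" in df.columns:
        flag(present("smoking") & ~df["smoking"].isin(SMOKING_LEVELS),
             f"smoking must be one of {SMOKING_LEVELS}")
    for col in ("sbp", "dbp", "total_chol", "ldl", "hdl", "triglycerides",
                "hscrp", "fasting_glucose", "bmi", "waist", "egfr", "acr"):
        if col in df.columns:
            flag(present(col) & (df[col] < 0), f"{col} must be non-negative")
    if "sbp" in df.columns and "dbp" in df.columns:
        both = present("sbp") & present("dbp")
        flag(both & (df["sbp"] <= df["dbp"]), "sbp>dbp violated")
    if "hba1c_pct" in df.columns:
        flag(present("hba1c_pct") & ~df["hba1c_pct"].between(3.0, 20.0),
             "hba1c_pct outside [3, 20] %")
    for c in CONDITIONS:
        col = f"family_history_{c}"
        if col in df.columns:
            flag(present(col) & ~df[col].isin([0, 1, 2]),
                 f"{col} must be in {{0,1,2}}")
        tcol = f"time_{c}"
        if tcol in df.columns:
            flag(present(tcol) & (df[tcol] <= 0), f"{tcol} must be positive")
    for col in sorted(BINARY_COLUMNS):
        if col in df.columns:
            flag(present(col) & ~df[col].isin([0, 1]), f"{col} must be 0/1")
    return pd.Series(reasons, index=df.index)


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort(
    path: str | Path,
    schema: dict[str, str] | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Read a delimited cohort file, validating every row.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, any other extension) file with a header.
    schema
        Optional mapping of file column names to canonical field names.
        A column mapped to (or named) ``hba1c_ifcc`` is converted to
        ``hba1c_pct``.

    Returns
    -------
    (cohort, rejections)
        The validated cohort, and a frame with one row per rejected input
        row (columns ``row``, ``id``, ``reason``).  Every input row ends
        up in exactly one of the two.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_delimiter(path), dtype=str,
                      keep_default_na=False, na_values=[""])
    if schema:
        raw = raw.rename(columns=schema)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns and not (col == "hba1c_pct" and "hba1c_ifcc" in raw.columns):
            raise ValueError(f"missing mandatory column: {col}")

    df = pd.DataFrame(index=raw.index)
    parse_fail = pd.Series([[] for _ in range(len(raw))], index=raw.index)
    for col in raw.columns:
        if col in STRING_COLUMNS:
            df[col] = raw[col]
            continue
        if col not in CANONICAL_COLUMNS and col != "hba1c_ifcc":
            continue  # unknown columns are ignored, not an error
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            parse_fail.iloc[i].append(f"unparseable numeric cell in '{col}'")
        df[col] = numeric
    if "hba1c_ifcc" in df.columns and "hba1c_pct" not in df.columns:
        df["hba1c_pct"] = ngsp_from_ifcc(df["hba1c_ifcc"])
    df = df.drop(columns=[c for c in ("hba1c_ifcc",) if c in df.columns])

    reasons = _row_violations(df)
    combined = parse_fail.combine(reasons, lambda a, b: a + b)
    bad_mask = combined.map(len) > 0
    rejections = pd.DataFrame({
        "row": np.flatnonzero(bad_mask.to_numpy()),
        "id": df.loc[bad_mask, "id"].to_numpy() if "id" in df.columns else None,
        "reason": ["; ".join(r) for r in combined[bad_mask]],
    })
    kept = df.loc[~bad_mask].reset_index(drop=True)
    ordered = [c for c in CANONICAL_COLUMNS if c in kept.columns]
    cohort = Cohort(kept[ordered])
    cohort.note(f"read {len(raw)} rows from {path.name}; rejected {len(rejections)}")
    return cohort, rejections


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as delimited text with canonical column names.

    Floats are serialised with 10 significant digits, so write-read-write
    reaches a byte-identical fixed point and values round-trip well beyond
    the 6-significant-digit contract.
    """
    path = Path(path)
    ordered = [c for c in CANONICAL_COLUMNS if c in cohort.data.columns]
    try:
        cohort.data[ordered].to_csv(
            path, sep=_delimiter(path), index=False, float_format="%.10g", na_rep=""
        )
    except OSError as exc:
        raise OSError(f"cannot write cohort file {path}: {exc}") from exc
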