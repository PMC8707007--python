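"""End-to-end orchestration: simulate/ingest -> exclude -> score ->
stratify -> evaluate, with a JSON report and TSV tables.

A run is fully determined by its configuration and seed: identical
``RunConfig`` + seed produce byte-identical reports.  Every number in the
report is produced by a stage whose intermediate artifact is written to
the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CONDITIONS, Cohort, read_cohort, write_cohort
from .eligibility import EligibilityConfig, apply_baseline_exclusions
from .framingham import FRS_FUNCTIONS, categorize_clinical
from .metrics import (auroc, build_reclassification, confusion_at_high,
                      delong_compare, nri, sens_spec)
from .prs import adjust_scores, bin_deciles, compute_prs, decile_incidence, filter_variants
from .rules import STRATIFY_FUNCTIONS, RuleConfig, advised_intervention
from .simulate import SimulationConfig, generate_cohort
from .survival import cumulative_incidence, fit_cox_strata, prs_decile_hrs

log = logging.getLogger("riskstrat")

#: Significance conventions: AUROC differences and stratum contrasts.
P_AUROC_DIFF = 0.01
P_STRATA = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    outdir: str | Path = "riskstrat_run"
    bootstrap_iters: int = 2000
    min_info: float = 0.4
    #: simulate when no cohort_path is given
    cohort_path: str | None = None
    dosage_path: str | None = None
    weights_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    #: bin rule-engine deciles on covariate-adjusted scores instead of raw
    use_adjusted_for_deciles: bool = False
    write_dosages: bool = False

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "simulation":
                for k, v in value.items():
                    setattr(cfg.simulation, k, v)
            elif key == "eligibility":
                for k, v in value.items():
                    setattr(cfg.eligibility, k, v)
            elif key == "conditions":
                cfg.conditions = tuple(value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key: {key}")
        return cfg


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _clean(obj):
    """Replace NaN with None recursively so the report is valid JSON."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report (also written
    to ``outdir/report.json`` with per-stage TSV artifacts)."""
    config.validate()
    outdir = Path(config.outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=16)

    # --- stage 1: cohort ------------------------------------------------
    if config.cohort_path:
        cohort, rejections = read_cohort(config.cohort_path)
        rejections.to_csv(outdir / "tables" / "ingest_rejections.tsv",
                          sep="\t", index=False)
        dosages = pd.read_csv(config.dosage_path, sep="\t", index_col=0) \
            if config.dosage_path else None
        weights = pd.read_csv(config.weights_path, sep="\t") \
            if config.weights_path else None
        truth = None
    else:
        sim = config.simulation
        sim.seed = int(rng_seeds[0])
        cohort, dosages, weights, truth = generate_cohort(sim)
        truth.to_csv(outdir / "tables" / "truth.tsv", sep="\t", index=False,
                     float_format="%.10g")
    write_cohort(cohort, outdir / "cohort.tsv")
    if weights is not None:
        weights.to_csv(outdir / "weights.tsv", sep="\t", index=False,
                       float_format="%.10g")
    if dosages is not None and config.write_dosages:
        dosages.to_csv(outdir / "dosages.tsv", sep="\t", float_format="%.10g")
    log.info("cohort: %d participants", cohort.n)

    # --- stage 2: eligibility --------------------------------------------
    analysis_cohorts, excl = apply_baseline_exclusions(cohort, config.eligibility)
    excl.table.to_csv(outdir / "tables" / "exclusions.tsv", sep="\t", index=False)
    with open(outdir / "tables" / "exclusion_summary.json", "w") as fh:
        json.dump(_clean({"n_input": excl.n_input, "sizes": excl.sizes,
                          "counts": excl.counts}), fh, indent=2, sort_keys=True)

    if weights is not None:
        weights_kept = filter_variants(weights, config.min_info)
    else:
        weights_kept = None

    report: dict = {
        "manifest": {
            "package": "riskstrat", "version": __version__,
            "seed": config.seed, "bootstrap_iters": config.bootstrap_iters,
            "conditions": list(config.conditions),
            "significance": {"auroc_diff": P_AUROC_DIFF, "strata": P_STRATA},
            "n_variants_after_info_filter":
                None if weights_kept is None else int(len(weights_kept)),
        },
        "exclusions": {"n_input": excl.n_input, "sizes": excl.sizes,
                       "counts": excl.counts},
        "conditions": {},
    }

    for ci, condition in enumerate(config.conditions):
        sub = analysis_cohorts[condition]
        df = sub.data
        n = len(df)
        events = df[f"event_{condition}"].to_numpy(dtype=bool)
        times = df[f"time_{condition}"].to_numpy(dtype=float)
        log.info("%s: n=%d, events=%d", condition, n, int(events.sum()))

        # clinical risk
        probs = FRS_FUNCTIONS[condition](df)
        clin_cat = categorize_clinical(probs, condition, sex=df["sex"])

        # genetic risk
        if dosages is not None and weights_kept is not None:
            raw = compute_prs(dosages.loc[df["id"]], weights_kept)
            covars = df[["pc1", "pc2", "pc3", "pc4", "genotyping_array"]].copy()
            covars["age"] = df["age"]
            covars["male"] = (df["sex"] == "male").astype(float)
            adjusted, _ = adjust_scores(raw, events.astype(int), covars)
            decile_basis = adjusted if config.use_adjusted_for_deciles \
                else raw.to_numpy()
            decs = bin_deciles(pd.Series(decile_basis, index=df.index))
            decs_adj = bin_deciles(pd.Series(adjusted, index=df.index))
        else:
            raise ValueError("dosage matrix and weight table are required")

        strat = STRATIFY_FUNCTIONS[condition](
            df, clin_cat, decs["decile"].to_numpy(), config.rules)
        advised = advised_intervention(strat["stratum"])
        frs_advised = clin_cat == "high"
        frs_low = clin_cat == "low"
        prs_advised = (decs["decile"] == 10).to_numpy()

        per_part = pd.DataFrame({
            "id": df["id"], "condition": condition,
            "frs_probability": probs, "frs_category": clin_cat,
            "prs_raw": raw.to_numpy(), "prs_adjusted": adjusted,
            "prs_decile": decs["decile"].to_numpy(),
            "prs_group": decs["group"].to_numpy(),
            "stratum": strat["stratum"].astype(str),
            "fired_rules": strat["fired_rules"],
            "advised": advised, "event": events.astype(int), "time": times,
        })
        per_part.to_csv(outdir / "tables" / f"{condition}_participants.tsv",
                        sep="\t", index=False, float_format="%.10g")

        seed_pool = np.random.default_rng(int(rng_seeds[ci + 1]))
        bseed = lambda: int(seed_pool.integers(0, 2**31 - 1))  # noqa: E731
        B = config.bootstrap_iters

        counts_rules = confusion_at_high(advised, events)
        counts_frs = confusion_at_high(frs_advised, events)
        stratum_ord = strat["stratum"].cat.codes.to_numpy()

        block: dict = {
            "n": n, "n_events": int(events.sum()),
            "person_years": float(times.sum()),
            "strata_counts": strat["stratum"].value_counts().to_dict(),
            "frs_category_counts": pd.Series(clin_cat).value_counts().to_dict(),
        }

        def metric_block(cc):
            return {name: est.to_dict() for name, est in sens_spec(cc).items()}

        block["rules"] = {
            "advised": int(advised.sum()),
            "advised_events": counts_rules.tp,
            "low_risk": int((strat["stratum"] == "NOT_ELEVATED").sum()),
            "low_risk_events": int(events[(strat["stratum"] == "NOT_ELEVATED").to_numpy()].sum()),
            "confusion": counts_rules.__dict__,
            "metrics": metric_block(counts_rules),
            "auroc": auroc(stratum_ord, events, n_boot=B, seed=bseed()).to_dict(),
        }
        block["framingham"] = {
            "advised": int(frs_advised.sum()),
            "advised_events": counts_frs.tp,
            "low_risk": int(frs_low.sum()),
            "low_risk_events": int(events[frs_low].sum()),
            "confusion": counts_frs.__dict__,
            "metrics": metric_block(counts_frs),
            "auroc": auroc(probs, events, n_boot=B, seed=bseed()).to_dict(),
        }
        block["prs"] = {
            "advised": int(prs_advised.sum()),
            "advised_events": int(events[prs_advised].sum()),
            "auroc": auroc(raw.to_numpy(), events, n_boot=B, seed=bseed()).to_dict(),
            "decile_incidence": decile_incidence(
                decs["decile"].to_numpy(), events).to_dict(orient="records"),
        }
        block["delong_rules_vs_frs"] = delong_compare(
            stratum_ord, probs, events).to_dict()

        recls = build_reclassification(frs_advised, advised, events)
        block["reclassification"] = recls.to_dict()
        block["nri"] = nri(recls).to_dict()
        if condition == "cad":
            by_sex = {}
            for sex in ("female", "male"):
                m = (df["sex"] == sex).to_numpy()
                tab = build_reclassification(frs_advised[m], advised[m], events[m])
                by_sex[sex] = {"reclassification": tab.to_dict(),
                               "nri": nri(tab).to_dict()}
            block["nri_by_sex"] = by_sex

        # survival layer
        horizon = config.simulation.horizon_years if not config.cohort_path \
            else float(times.max())
        try:
            surv = fit_cox_strata(times, events, strat["stratum"].astype(str),
                                  reference="NOT_ELEVATED", horizon=horizon)
            block["stratum_hr"] = surv.to_dict()
        except (ValueError, RuntimeError) as exc:
            block["stratum_hr"] = {"error": str(exc)}
        try:
            frs_surv = fit_cox_strata(times, events, clin_cat, reference="low",
                                      horizon=horizon)
            block["frs_stratum_hr"] = frs_surv.to_dict()
        except (ValueError, RuntimeError) as exc:
            block["frs_stratum_hr"] = {"error": str(exc)}
        block["prs_decile_hr"] = {
            contrast: prs_decile_hrs(times, events,
                                     decs_adj["decile"].to_numpy(), contrast)
            for contrast in ("top_vs_rest", "top_vs_1to7", "8and9_vs_1to7")
        }

        curves = cumulative_incidence(times, events, decs["group"].to_numpy())
        curves.to_csv(outdir / "tables" / f"{condition}_prs_group_incidence.tsv",
                      sep="\t", index=False, float_format="%.10g")
        report["conditions"][condition] = block

    report = _clean(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
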