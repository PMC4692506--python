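"""End-to-end analysis pipeline and report generation.

Runs the full study analysis on one cohort: Hardy-Weinberg tests on
controls, single-locus case-control chi-square per stratum with a
Bonferroni flag, the exhaustive MDR search with cross-validation and an
optional permutation test, full-data cell labeling of the best model,
per-individual risk recoding, and crude plus covariate-adjusted logistic
odds ratios for the high-risk-combination dichotomy, overall and per
stroke subtype. All randomness fans out from one master seed (fold seed =
master + 1, permutation seed = master + 2) and every reported number is
recomputable from cohort + config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mdr, stats
from .cohort import Cohort, genotype_table

log = logging.getLogger("epimdr")

DEFAULT_COVARIATES = ["age", "sex", "family_history_IS", "hypertension", "diabetes"]


@dataclass
class PipelineConfig:
    strata: list[str] = field(default_factory=lambda: ["overall", "LAA", "SAO"])
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    orders: tuple[int, ...] = (1, 2, 3, 4)
    cv_folds: int = 10
    n_permutations: int = 1000
    run_permutation: bool = True
    min_stratum_cases: int = 30
    seed: int = 0

    def fold_seed(self) -> int:
        return self.seed + 1

    def permutation_seed(self) -> int:
        return self.seed + 2

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    hwe: pd.DataFrame
    single_locus: pd.DataFrame
    mdr_models: pd.DataFrame
    cell_grid: pd.DataFrame
    risk_tables: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        """Deterministic machine-readable rendering of every block."""
        blocks = {
            "hwe": self.hwe.to_dict(orient="records"),
            "single_locus": self.single_locus.to_dict(orient="records"),
            "mdr_models": self.mdr_models.to_dict(orient="records"),
            "cell_grid": self.cell_grid.to_dict(orient="records"),
            "risk_tables": self.risk_tables.to_dict(orient="records"),
            "provenance": self.provenance,
        }
        return json.dumps(blocks, sort_keys=True, indent=1, default=str)


def _skip_small_strata(cohort: Cohort, strata: list[str], minimum: int) -> list[str]:
    kept = []
    for s in strata:
        n = cohort.n_cases if s == "overall" else cohort.stratum(s).n_cases
        if n < minimum:
            log.warning("stratum %s skipped: %d cases < minimum %d", s, n, minimum)
        else:
            kept.append(s)
    return kept


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> AnalysisReport:
    config = config if config is not None else PipelineConfig()
    strata = _skip_small_strata(cohort, config.strata, config.min_stratum_cases)
    if "overall" not in strata:
        raise ValueError("overall stratum is required (too few cases?)")

    # 1. HWE on controls, per locus
    log.info("HWE tests on %d controls", cohort.n_controls)
    hwe_rows = []
    controls = cohort.subset(cohort.phenotype == 0)
    for locus in cohort.loci:
        tab = genotype_table(controls, locus.name)
        res = stats.hwe_chisq(tab.counts[:, 0], locus)
        hwe_rows.append({"locus": locus.name, "chi2": res.statistic, "df": res.df,
                         "p": res.p_value, "n": res.n_used})
    hwe_df = pd.DataFrame(hwe_rows)

    # 2. single-locus chi-square per stratum, Bonferroni over loci
    thr = stats.bonferroni_threshold(0.05, len(cohort.loci))
    sl_rows = []
    for s in strata:
        for locus in cohort.loci:
            tab = genotype_table(cohort, locus.name, stratum=None if s == "overall" else s)
            res = stats.chisq_independence(tab)
            sl_rows.append({"stratum": s, "locus": locus.name, "chi2": res.statistic,
                            "df": res.df, "p": res.p_value,
                            "bonferroni_significant": bool(res.p_value < thr),
                            "n": res.n_used, "excluded_missing": tab.n_excluded})
    sl_df = pd.DataFrame(sl_rows)

    # 3. MDR search (with permutation test) per stratum
    mdr_rows = []
    best_overall = None
    for s in strata:
        sub = cohort.stratum(None if s == "overall" else s)
        log.info("MDR search, stratum %s: %d cases / %d controls",
                 s, sub.n_cases, sub.n_controls)
        if config.run_permutation:
            pval, result = mdr.permutation_test(
                sub, orders=config.orders, folds_seed=config.fold_seed(),
                n_perm=config.n_permutations, seed=config.permutation_seed(),
                k=config.cv_folds)
        else:
            result = mdr.mdr_search(sub, orders=config.orders, k=config.cv_folds,
                                    fold_seed=config.fold_seed())
        tab = result.table()
        tab.insert(0, "stratum", s)
        tab["selected"] = [result.per_order[o].combo == result.best.combo
                           for o in sorted(result.per_order)]
        mdr_rows.append(tab)
        if s == "overall":
            best_overall = result.best
    mdr_df = pd.concat(mdr_rows, ignore_index=True)

    # 4. full-data labeling of the overall best model + risk recode
    labels = mdr.label_cells(cohort, best_overall.combo)
    grid = labels.grid_frame(cohort)

    # 5. crude + adjusted odds ratios of the high/low dichotomy per stratum
    risk_rows = []
    have_covs = all(c in cohort.data.columns for c in config.covariates)
    for s in strata:
        table = mdr.classify_individuals(cohort, labels,
                                         stratum=None if s == "overall" else s)
        crude = stats.odds_ratio(table)
        row = {"stratum": s, "model": ", ".join(best_overall.combo),
               "cases_high": int(table.counts[0, 0]), "cases_low": int(table.counts[1, 0]),
               "controls_high": int(table.counts[0, 1]), "controls_low": int(table.counts[1, 1]),
               "crude_or": crude.odds_ratio, "crude_ci_low": crude.ci_low,
               "crude_ci_high": crude.ci_high, "crude_p": crude.p_value}
        if have_covs:
            sub = cohort.stratum(None if s == "overall" else s)
            rec = mdr.reduce(sub, labels)
            # a rare covariate can quasi-separate inside a small stratum;
            # drop it from that stratum's model rather than aborting
            covs = list(config.covariates)
            while True:
                try:
                    fit = stats.adjusted_logistic(sub, rec.indicator, rec.used,
                                                  covs, name="high_risk")
                    break
                except stats.SeparationError as exc:
                    bad = [p for p in getattr(exc, "predictors", []) if p in covs]
                    if not bad:
                        raise
                    log.warning("stratum %s: dropping quasi-separated covariate(s) %s", s, bad)
                    covs = [cv for cv in covs if cv not in bad]
            if covs != list(config.covariates):
                row["adjusted_covariates"] = ",".join(covs)
            row.update({"adjusted_or": float(fit.odds_ratios["high_risk"]),
                        "adjusted_ci_low": float(fit.ci_low["high_risk"]),
                        "adjusted_ci_high": float(fit.ci_high["high_risk"]),
                        "adjusted_p": float(fit.p_values["high_risk"])})
        risk_rows.append(row)
    risk_df = pd.DataFrame(risk_rows)

    from . import __version__

    provenance = {"seed": config.seed, "fold_seed": config.fold_seed(),
                  "permutation_seed": config.permutation_seed(),
                  "config_hash": config.config_hash(), "version": __version__,
                  "n_cases": cohort.n_cases, "n_controls": cohort.n_controls,
                  "bonferroni_threshold": thr,
                  "best_model": list(best_overall.combo)}
    return AnalysisReport(hwe=hwe_df, single_locus=sl_df, mdr_models=mdr_df,
                          cell_grid=grid, risk_tables=risk_df, provenance=provenance)


def report_render(report: AnalysisReport, outdir, formats=("tsv", "json", "txt")) -> list[Path]:
    """Write the report blocks; TSV tables, a JSON bundle, a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    known = {"tsv", "json", "txt"}
    unknown = set(formats) - known
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    if "tsv" in formats:
        for name, df in (("hwe", report.hwe), ("single_locus", report.single_locus),
                         ("mdr_models", report.mdr_models), ("cell_grid", report.cell_grid),
                         ("risk_tables", report.risk_tables)):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
    if "json" in formats:
        p = outdir / "results.json"
        p.write_text(report.to_json())
        written.append(p)
    if "txt" in formats:
        lines = ["epimdr analysis report", "======================", "",
                 f"best MDR model: {', '.join(report.provenance['best_model'])}",
                 f"seed: {report.provenance['seed']}  config: {report.provenance['config_hash']}",
                 "", "MDR models by order:", report.mdr_models.to_string(index=False),
                 "", "Risk-combination odds ratios:", report.risk_tables.to_string(index=False),
                 ""]
        p = outdir / "report.txt"
        p.write_text("\n".join(lines))
        written.append(p)
    return written
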