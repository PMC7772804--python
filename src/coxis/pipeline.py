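"""End-to-end orchestration: load/simulate -> normalize -> score -> analyze.

A run is described by a :class:`RunConfig` (loadable from a YAML/flat
key-value file), executes its stages in a fixed order, and leaves a
machine-readable provenance log (parameters, package version, sample and
gene counts in and out per stage) next to its outputs.  Stages whose
inputs are absent are skipped with an explicit log entry; everything else
fails loudly with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ClinicalTable, CoxisError, ExpressionMatrix, ResponseTable, Scale
from .icb import (
    deviance_explained,
    logistic_fit,
    nested_model_test,
    pool_responses,
    roc_auc,
    signature_benchmark,
)
from .io import exclude_on_treatment, read_clinical, read_expression, read_response
from .normalize import normalize_counts, zscore_genes
from .scoring import ScoreTable, coxis_score, mean_signature_score
from .signatures import builtin_coxis, builtin_marker_sets
from .survival import cox_fit, km_estimate, logrank_test, optimal_cutoff, stratify

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    expression_path: str | None = None
    expression_scale: str = "counts"
    clinical_path: str | None = None
    response_path: str | None = None
    simulate: bool = False
    seed: int = 0
    stratification_mode: str = "median"       # median | optimal | quantiles
    k_quantiles: int = 4
    covariates: tuple[str, ...] = ()
    pooling_convention: str = "sd_nonresponder"
    cpm_threshold: float = 0.25
    sample_fraction: float = 0.10
    simulation_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise CoxisError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate and self.expression_path is None:
            raise CoxisError("config needs either simulate: true or an expression_path")
        for key in ("expression_path", "clinical_path", "response_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise CoxisError(f"{key} does not exist: {p}")
        if self.stratification_mode not in ("median", "optimal", "quantiles"):
            raise CoxisError(f"unknown stratification_mode {self.stratification_mode!r}")


def _stage(provenance: list, name: str, **info) -> None:
    entry = {"stage": name, **info}
    provenance.append(entry)
    log.info("stage %s: %s", name, info)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline described by ``config``; returns the report dict.

    Writes scores.tsv, fit.json (survival), icb_report.json and run_log.json
    into ``config.out_dir`` (stages without inputs are skipped and logged).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: list[dict] = []
    report: dict = {"seed": config.seed, "version": __version__}

    # ---- acquire inputs -------------------------------------------------
    clinical: ClinicalTable | None = None
    response: ResponseTable | None = None
    if config.simulate:
        from .simulate import SimulationConfig, simulate_cohort

        sim_cfg = SimulationConfig(**config.simulation_overrides)
        cohort = simulate_cohort(sim_cfg, seed=config.seed)
        expr, clinical, response = cohort.expression, cohort.clinical, cohort.response
        _stage(provenance, "simulate", seed=config.seed,
               n_samples=expr.n_samples, n_genes=expr.n_genes)
    else:
        expr = read_expression(config.expression_path, scale=config.expression_scale)
        _stage(provenance, "load_expression", path=config.expression_path,
               n_samples=expr.n_samples, n_genes=expr.n_genes,
               scale=expr.scale.value)
        if config.clinical_path:
            clinical = read_clinical(config.clinical_path)
            _stage(provenance, "load_clinical", n=len(clinical.sample_ids))
        if config.response_path:
            response = read_response(config.response_path)
            _stage(provenance, "load_response", n=len(response.sample_ids))

    # ---- normalize ------------------------------------------------------
    if expr.scale is Scale.COUNTS:
        n_before = expr.n_genes
        log2m = normalize_counts(expr, cpm_threshold=config.cpm_threshold,
                                 sample_fraction=config.sample_fraction)
        _stage(provenance, "normalize", genes_in=n_before,
               genes_out=log2m.n_genes,
               cpm_threshold=config.cpm_threshold,
               sample_fraction=config.sample_fraction)
    elif expr.scale is Scale.LINEAR:
        from .normalize import log2_plus1

        log2m = log2_plus1(expr)
        _stage(provenance, "log2_transform", genes=log2m.n_genes)
    else:
        log2m = expr
        _stage(provenance, "normalize", skipped="input already log2")

    # ---- score ----------------------------------------------------------
    pair = builtin_coxis()
    table = coxis_score(log2m, pair)
    markers = builtin_marker_sets()
    for name in markers.names():
        try:
            st = mean_signature_score(log2m, markers.get(name))
            table.add(name, st.scores[name], st.metadata[name])
        except CoxisError as err:
            log.warning("marker set %s not scored: %s", name, err)
    scores_path = out / "scores.tsv"
    table.scores.to_csv(scores_path, sep="\t", float_format="%.10g")
    _stage(provenance, "score", columns=list(table.scores.columns),
           out=str(scores_path))
    coxis = table.scores["COX-IS"]
    report["coxis_summary"] = {
        "mean": float(coxis.mean()), "sd": float(coxis.std()),
        "min": float(coxis.min()), "max": float(coxis.max()),
    }

    # ---- survival -------------------------------------------------------
    if clinical is None:
        _stage(provenance, "survival", skipped="no clinical input")
    else:
        common = coxis.index.intersection(clinical.data.index)
        cl = ClinicalTable(data=clinical.data.loc[common])
        s = coxis.loc[common]
        if config.stratification_mode == "optimal":
            strat = optimal_cutoff(s, cl)
        elif config.stratification_mode == "quantiles":
            strat = stratify(s, k_quantiles=config.k_quantiles)
        else:
            strat = stratify(s, mode="median")
        lr = logrank_test(cl.times, cl.events, strat.labels.to_numpy())
        z = (s - s.mean()) / s.std(ddof=1)
        fit = cox_fit(cl, scores=z, score_name="coxis_z",
                      covariates=tuple(c for c in config.covariates
                                       if c in cl.data.columns))
        km_rows = []
        for grp in sorted(strat.labels.unique()):
            mask = (strat.labels == grp).to_numpy()
            curve = km_estimate(cl.times[mask], cl.events[mask])
            for t, sv in zip(curve.times, curve.survival):
                km_rows.append({"group": grp, "time": t, "survival": sv})
        pd.DataFrame(km_rows).to_csv(out / "km.tsv", sep="\t", index=False)
        surv_report = {
            "stratification": {
                "mode": strat.cutoff_type,
                "cutoffs": strat.cutoffs,
                "group_sizes": strat.group_sizes,
                "candidate_pvalues": strat.candidate_pvalues,
            },
            "logrank": {"statistic": lr.statistic, "df": lr.df, "p": lr.p_value},
            "cox": {
                "n": fit.n, "n_events": fit.n_events,
                "variables": {
                    var: {"coef": float(row["coef"]), "hr": float(row["hr"]),
                          "ci": [float(row["hr_low"]), float(row["hr_high"])],
                          "p": float(row["p"])}
                    for var, row in fit.table.iterrows()
                },
            },
        }
        (out / "fit.json").write_text(json.dumps(surv_report, indent=2))
        report["survival"] = surv_report
        _stage(provenance, "survival", n=fit.n, n_events=fit.n_events,
               logrank_p=lr.p_value)

    # ---- ICB response ---------------------------------------------------
    if response is None:
        _stage(provenance, "icb", skipped="no response input")
    else:
        baseline = exclude_on_treatment(response)
        pooled = pool_responses(baseline, convention=config.pooling_convention)
        y = pooled.responder
        common = coxis.index.intersection(y.index)
        y = y.loc[common]
        if y.nunique() < 2:
            _stage(provenance, "icb", skipped="single response class")
        else:
            bench = signature_benchmark(table, y)
            auc = roc_auc(coxis.loc[common].to_numpy(), y.to_numpy(),
                          low_score_is_positive=True)
            cz = (coxis.loc[common] - coxis.loc[common].mean()) / coxis.loc[common].std(ddof=1)
            preds = pd.DataFrame({"coxis_z": cz})
            covs = pd.DataFrame(index=common)
            if "tmb" in baseline.data.columns:
                covs["tmb"] = baseline.data.loc[common, "tmb"]
            if "pdl1_ic" in baseline.data.columns:
                covs["pdl1_ic"] = baseline.data.loc[common, "pdl1_ic"].astype(str)
            icb_report: dict = {
                "convention": pooled.convention,
                "n": int(len(y)),
                "n_responders": int(y.sum()),
                "n_ne_dropped": pooled.n_ne_dropped,
                "coxis_auc": auc,
                "benchmark": bench.reset_index().to_dict(orient="records"),
            }
            fit_score = logistic_fit(y, preds)
            icb_report["deviance_explained_coxis"] = deviance_explained(fit_score)
            if not covs.empty:
                covs_clean = covs.dropna()
                idx = covs_clean.index.intersection(y.index)
                small = logistic_fit(y.loc[idx], covs_clean.loc[idx])
                both = covs_clean.loc[idx].join(preds.loc[idx])
                large = logistic_fit(y.loc[idx], both)
                stat, dfree, p = nested_model_test(small, large)
                icb_report["nested_covariates_plus_coxis"] = {
                    "chi2": stat, "df": dfree, "p": p,
                    "deviance_explained_small": deviance_explained(small),
                    "deviance_explained_large": deviance_explained(large),
                }
            (out / "icb_report.json").write_text(json.dumps(icb_report, indent=2))
            report["icb"] = icb_report
            _stage(provenance, "icb", n=int(len(y)), auc=auc)

    run_log = {"config": {**asdict(config)}, "seed": config.seed,
               "version": __version__, "stages": provenance}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    report["stages"] = provenance
    return report
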