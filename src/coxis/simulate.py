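"""Synthetic tumor cohorts with the statistical structure the analysis assumes.

Each cohort plants, per sample, two anti-correlated latent inflammation
activities: a cancer-promoting activity ``a`` and a cancer-inhibitory
activity ``b = rho * a + sqrt(1 - rho^2) * eps`` with ``rho <= 0``.
Cancer-promoting genes (and the PTGS2-like anchor) load on ``a``,
cancer-inhibitory genes on ``b``; background genes load on neither.
Read counts are negative-binomial around library-size-scaled expected
abundances, so the CPM -> filter -> log2 pipeline is exercised under
realistic overdispersion.  Overall survival is exponential with hazard
proportional to ``exp(beta * z)`` where ``z`` is the standardized
noise-free COX-IS, censored by an independent uniform censoring time
calibrated to the requested censoring fraction.  Response to checkpoint
blockade is Bernoulli with logit linear in the standardized inhibitory
minus promoting activity (``b - a``), plus partially informative TMB and
PD-L1 terms.

A truth record accompanies every cohort so parameter-recovery tests never
re-derive planted values from the generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import (
    ClinicalTable,
    CoxisError,
    ExpressionMatrix,
    ResponseTable,
    Scale,
)
from .signatures import CI_GENES, CP_GENES

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort",
           "simulate_null_cohort", "ANCHOR_GENE"]

ANCHOR_GENE = "PTGS2"


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    Defaults describe a mid-sized bulk RNA-seq cohort: 200 tumors, the
    24 signature genes plus the anchor and 475 background genes, a strong
    antagonism (rho = -0.6) between the two inflammation programs, hazard
    doubling per SD of the true score (beta = ln 2), 30% censoring, and a
    response rate near 30% driven mostly by the inhibitory-minus-promoting
    activity with weaker TMB and PD-L1 contributions.
    """

    n_samples: int = 200
    n_background_genes: int = 475
    rho: float = -0.6                      # latent CP-CI correlation, in [-1, 0]
    cp_loading_mean: float = 1.0           # log2-units shift per SD of latent
    cp_loading_sd: float = 0.2
    ci_loading_mean: float = 1.0
    ci_loading_sd: float = 0.2
    anchor_loading: float = 1.0
    signature_base_log2: float = 5.0       # baseline log2 relative abundance
    signature_base_sd: float = 0.75
    background_log2_low: float = 0.0
    background_log2_high: float = 8.0
    dispersion: float = 0.3                # negative-binomial dispersion
    libsize_mean: float = 2.0e6
    libsize_log_sd: float = 0.3
    baseline_hazard: float = 0.23          # events per year at z = 0
    beta: float = float(np.log(2.0))       # log-HR per SD of true COX-IS
    censoring_rate: float = 0.30
    response_intercept: float = -0.85      # alpha on the logit scale
    gamma: float = 1.0                     # coef on standardized (b - a)
    tmb_log_mean: float = float(np.log(5.0))
    tmb_log_sd: float = 1.0
    tmb_coef: float = 0.5                  # on the standardized log10 TMB
    pdl1_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # IC0/IC1/IC2+
    pdl1_coef: float = 0.3                 # per ordinal level
    on_treatment_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise CoxisError("invalid config field n_samples: need >= 4")
        if not -1.0 <= self.rho <= 0.0:
            raise CoxisError("invalid config field rho: must lie in [-1, 0]")
        for name in ("dispersion", "libsize_log_sd", "cp_loading_sd",
                     "ci_loading_sd", "signature_base_sd", "tmb_log_sd"):
            if getattr(self, name) < 0:
                raise CoxisError(f"invalid config field {name}: must be >= 0")
        if self.baseline_hazard <= 0:
            raise CoxisError("invalid config field baseline_hazard: must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise CoxisError("invalid config field censoring_rate: must be in [0, 1)")
        if not np.isclose(sum(self.pdl1_probs), 1.0):
            raise CoxisError("invalid config field pdl1_probs: must sum to 1")
        if any(p < 0 for p in self.pdl1_probs):
            raise CoxisError("invalid config field pdl1_probs: must be non-negative")
        if not 0.0 <= self.on_treatment_fraction < 1.0:
            raise CoxisError("invalid config field on_treatment_fraction")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    expression: ExpressionMatrix          # raw counts
    clinical: ClinicalTable
    response: ResponseTable
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture.

    var = mean + dispersion * mean^2; dispersion 0 degenerates to Poisson.
    """
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _uniform_censoring_bound(hazards: np.ndarray, target: float) -> float:
    """Solve for c so that C ~ U(0, c) censors the target fraction on average.

    For T ~ Exp(h), P(T > C) = (1 - exp(-h c)) / (h c); averaged over the
    cohort's hazards and solved by bisection.
    """

    def censored_fraction(c: float) -> float:
        x = hazards * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9
    # censored_fraction is decreasing in c, -> 1 as c -> 0 and -> 0 as c -> inf
    return brentq(lambda c: censored_fraction(c) - target, lo, hi, xtol=1e-10)


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate one cohort under ``config`` with an explicit ``seed``.

    All randomness flows from the single seed; identical config + seed
    gives bit-identical cohorts.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    if seed is None:
        raise CoxisError("simulate_cohort requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # latent program activities per sample
    a = rng.standard_normal(n)                       # cancer-promoting activity
    eps = rng.standard_normal(n)
    b = cfg.rho * a + np.sqrt(1.0 - cfg.rho ** 2) * eps  # cancer-inhibitory

    genes = list(CP_GENES) + list(CI_GENES) + [ANCHOR_GENE] + [
        f"BG{i:04d}" for i in range(cfg.n_background_genes)
    ]
    n_cp, n_ci = len(CP_GENES), len(CI_GENES)
    n_genes = len(genes)

    base = np.empty(n_genes)
    base[: n_cp + n_ci + 1] = rng.normal(cfg.signature_base_log2,
                                         cfg.signature_base_sd, n_cp + n_ci + 1)
    base[n_cp + n_ci + 1:] = rng.uniform(cfg.background_log2_low,
                                         cfg.background_log2_high,
                                         cfg.n_background_genes)
    loadings = np.zeros(n_genes)
    loadings[:n_cp] = rng.normal(cfg.cp_loading_mean, cfg.cp_loading_sd, n_cp)
    loadings[n_cp:n_cp + n_ci] = rng.normal(cfg.ci_loading_mean,
                                            cfg.ci_loading_sd, n_ci)
    loadings[n_cp + n_ci] = cfg.anchor_loading

    latent = np.zeros((n_genes, n))
    latent[:n_cp] = a
    latent[n_cp:n_cp + n_ci] = b
    latent[n_cp + n_ci] = a                          # anchor follows CP activity

    log2_rel = base[:, None] + loadings[:, None] * latent
    rel = np.exp2(log2_rel)
    frac = rel / rel.sum(axis=0, keepdims=True)

    libsizes = cfg.libsize_mean * np.exp(
        rng.normal(0.0, cfg.libsize_log_sd, n) - 0.5 * cfg.libsize_log_sd ** 2
    )
    counts = _nb_counts(rng, frac * libsizes[None, :], cfg.dispersion)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts.astype(np.int64), index=genes, columns=sample_ids),
        scale=Scale.COUNTS,
    )

    # noise-free COX-IS from the expected log2(CPM + 1) values
    cpm_true = frac * 1.0e6
    e_true = np.log2(cpm_true + 1.0)
    true_score = e_true[:n_cp].mean(axis=0) / e_true[n_cp:n_cp + n_ci].mean(axis=0)
    z = (true_score - true_score.mean()) / true_score.std(ddof=0)

    # survival: exponential hazard increasing with the true score
    hazards = cfg.baseline_hazard * np.exp(cfg.beta * z)
    event_times = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        c_max = _uniform_censoring_bound(hazards, cfg.censoring_rate)
        censor_times = rng.uniform(0.0, c_max, n)
        os_time = np.minimum(event_times, censor_times)
        os_event = (event_times <= censor_times).astype(int)
    else:
        os_time = event_times
        os_event = np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-6)

    age = rng.normal(62.0, 10.0, n).round(1)
    sex = rng.choice(["F", "M"], size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.2, 0.3, 0.3, 0.2])
    clinical = ClinicalTable(data=pd.DataFrame({
        "os_time": os_time,
        "os_event": os_event,
        "age": age,
        "sex": sex,
        "stage": stage.astype(float),
    }, index=pd.Index(sample_ids, name="sample_id")))

    # ICB response: logit linear in standardized (b - a) plus TMB / PD-L1
    diff = b - a
    diff_z = (diff - diff.mean()) / diff.std(ddof=0)
    tmb = rng.lognormal(cfg.tmb_log_mean, cfg.tmb_log_sd, n)
    log_tmb = np.log10(tmb + 1.0)
    tmb_z = (log_tmb - log_tmb.mean()) / log_tmb.std(ddof=0)
    pdl1_level = rng.choice([0, 1, 2], size=n, p=list(cfg.pdl1_probs))
    logit = (cfg.response_intercept + cfg.gamma * diff_z
             + cfg.tmb_coef * tmb_z + cfg.pdl1_coef * pdl1_level)
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = rng.binomial(1, p_resp)
    # map responders to CR/PR and non-responders to SD/PD so either pooling
    # convention can be exercised against the planted truth
    cat_draw = rng.uniform(size=n)
    category = np.where(responder == 1,
                        np.where(cat_draw < 0.3, "CR", "PR"),
                        np.where(cat_draw < 0.35, "SD", "PD"))
    timepoint = np.where(rng.uniform(size=n) < cfg.on_treatment_fraction,
                         "on_treatment", "baseline")
    response = ResponseTable(data=pd.DataFrame({
        "category": category,
        "tmb": tmb,
        "pdl1_ic": pd.Categorical.from_codes(pdl1_level, ["IC0", "IC1", "IC2+"],
                                             ordered=True),
        "timepoint": timepoint,
    }, index=pd.Index(sample_ids, name="sample_id")))

    truth = {
        "seed": int(seed),
        "config": asdict(cfg),
        "cp_activity": a,
        "ci_activity": b,
        "true_coxis": true_score,
        "true_coxis_z": z,
        "beta": cfg.beta,
        "gamma": cfg.gamma,
        "rho": cfg.rho,
        "response_probability": p_resp,
        "responder": responder,
        "hazards": hazards,
        "gene_loadings": dict(zip(genes, loadings)),
    }
    return SimulatedCohort(expression=expr, clinical=clinical,
                           response=response, truth=truth)


def simulate_null_cohort(config: SimulationConfig | None = None,
                         seed: int | None = None) -> SimulatedCohort:
    """A cohort with no planted structure: rho = 0, beta = 0, gamma = 0.

    Used for type-I-error calibration of the downstream tests.
    """
    cfg = config if config is not None else SimulationConfig()
    from dataclasses import replace

    null_cfg = replace(cfg, rho=0.0, beta=0.0, gamma=0.0,
                       tmb_coef=0.0, pdl1_coef=0.0)
    return simulate_cohort(null_cfg, seed=seed)
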