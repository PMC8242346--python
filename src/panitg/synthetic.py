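"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the statistical structure of TCGA-style per-cancer bundles:
log2 expression with a tumor/normal shift for planted dysregulated
genes, continuous per-gene copy-number values coupled to tumor
expression, methylation beta-values (logit-normal, so support stays in
[0, 1]) with a planted tumor-normal difference and negative coupling to
expression, Weibull proportional-hazards survival linked to planted
prognostic genes, ordinal TNM/stage/gender/age covariates, and
Bernoulli per-gene mutations emitted as MAF records. Every cohort
carries a machine-readable truth table so downstream screens can be
scored for recall and false-discovery proportion.

Coupling strengths are specified as the *target Pearson correlation*
between the omic value and tumor expression: a target r is converted to
an additive coefficient c = r / sqrt(1 - r^2) applied to the
standardized omic value scaled by the expression noise SD, which makes
the realized sample correlation concentrate around r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CLINICAL_COLUMNS, MAF_COLUMNS, NORMAL, TUMOR, OmicsCohort
from .genes import ITG_PANEL

__all__ = [
    "CohortConfig",
    "CnvDriverSpec",
    "MethDriverSpec",
    "ConfigError",
    "generate_cohort",
    "generate_pan_cancer",
]


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class CnvDriverSpec:
    """Planted copy-number driver.

    direction: "gain" or "loss"; alteration_fraction: fraction of tumor
    samples carrying the alteration; cnv_magnitude: mean |CNV| in
    altered samples; coupling_strength: target |Pearson r| between CNV
    and tumor expression.
    """

    direction: str
    alteration_fraction: float
    cnv_magnitude: float
    coupling_strength: float


@dataclass(frozen=True)
class MethDriverSpec:
    """Planted methylation driver.

    direction: "hyper" (tumor beta higher) or "hypo"; delta_beta:
    target mean tumor beta minus mean normal beta (magnitude);
    coupling_strength: target |Pearson r| between beta and tumor
    expression (realized correlation is negative).
    """

    direction: str
    delta_beta: float
    coupling_strength: float


# substream offsets: one independent generator per omic
_STREAMS = {
    "expression": 0,
    "cnv": 1,
    "methylation": 2,
    "survival": 3,
    "mutation": 4,
    "clinical": 5,
}

_NONSYN_MIX = [
    ("Missense_Mutation", "SNP", 0.60),
    ("Nonsense_Mutation", "SNP", 0.10),
    ("Splice_Site", "SNP", 0.07),
    ("Frame_Shift_Del", "DEL", 0.05),
    ("In_Frame_Ins", "INS", 0.03),
    ("Silent", "SNP", 0.15),
]

_NT = np.array(list("ACGT"))

# default six-category substitution spectrum for SNV emission
# (C>T transitions predominate, as in most solid tumors)
_SPECTRUM_PRIOR = {
    "C>A": 0.15, "C>G": 0.08, "C>T": 0.40,
    "T>A": 0.07, "T>C": 0.20, "T>G": 0.10,
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CohortConfig:
    """Full specification of one synthetic cancer cohort.

    All planted-gene maps must reference genes in ``gene_panel``.
    ``n_genes`` may exceed the panel size; the surplus is filled with
    null background genes named ``GENE####`` (useful as a ranking
    universe for enrichment testing and for null calibration).
    """

    cancer_code: str
    n_tumor: int = 100
    n_normal: int = 50
    n_genes: int | None = None
    gene_panel: tuple = tuple(ITG_PANEL)
    planted_up: dict = field(default_factory=dict)
    planted_down: dict = field(default_factory=dict)
    planted_cnv_drivers: dict = field(default_factory=dict)
    planted_meth_drivers: dict = field(default_factory=dict)
    planted_prognostic: dict = field(default_factory=dict)
    mutation_rate_per_gene: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_hazard_scale: float = 60.0  # months
    baseline_hazard_shape: float = 1.2
    censoring_rate: float = 0.3
    max_follow_up: float = 240.0  # months, administrative truncation
    beta_logit_sd: float = 0.5
    cnv_noise_sd: float = 0.05
    missing_clinical_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes is None:
            self.n_genes = len(self.gene_panel)
        self.gene_panel = tuple(self.gene_panel)
        self.planted_cnv_drivers = {
            g: (CnvDriverSpec(*v) if not isinstance(v, CnvDriverSpec) else v)
            for g, v in self.planted_cnv_drivers.items()
        }
        self.planted_meth_drivers = {
            g: (MethDriverSpec(*v) if not isinstance(v, MethDriverSpec) else v)
            for g, v in self.planted_meth_drivers.items()
        }
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.cancer_code:
            raise ConfigError("cancer_code: must be a non-empty label")
        for name in ("n_tumor", "n_normal"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 2:
                raise ConfigError(f"{name}: must be an integer >= 2 (got {v!r})")
        if len(set(self.gene_panel)) != len(self.gene_panel):
            raise ConfigError("gene_panel: contains duplicate gene names")
        if self.n_genes < len(self.gene_panel):
            raise ConfigError(
                f"n_genes: must be >= len(gene_panel)={len(self.gene_panel)} "
                f"(got {self.n_genes})"
            )
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigError(f"censoring_rate: must be in [0, 1] (got {self.censoring_rate})")
        for name in ("noise_sd", "baseline_hazard_scale", "baseline_hazard_shape",
                     "max_follow_up", "beta_logit_sd", "cnv_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0 (got {getattr(self, name)})")
        if not 0.0 <= self.missing_clinical_rate <= 1.0:
            raise ConfigError("missing_clinical_rate: must be in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed: must be a non-negative integer (got {self.seed!r})")

        panel = set(self.gene_panel)
        for name in ("planted_up", "planted_down", "planted_cnv_drivers",
                     "planted_meth_drivers", "planted_prognostic",
                     "mutation_rate_per_gene"):
            extra = set(getattr(self, name)) - panel
            if extra:
                raise ConfigError(
                    f"{name}: genes not in gene_panel: {sorted(extra)}"
                )
        overlap = set(self.planted_cnv_drivers) & set(self.planted_meth_drivers)
        if overlap:
            raise ConfigError(
                f"planted_cnv_drivers/planted_meth_drivers: genes planted with "
                f"both mechanisms: {sorted(overlap)}"
            )
        for g, spec in self.planted_cnv_drivers.items():
            if spec.direction not in ("gain", "loss"):
                raise ConfigError(
                    f"planted_cnv_drivers[{g}].direction: must be 'gain' or 'loss'"
                )
            if not 0.0 <= spec.alteration_fraction <= 1.0:
                raise ConfigError(
                    f"planted_cnv_drivers[{g}].alteration_fraction: must be in [0, 1]"
                )
            if not 0.0 <= spec.coupling_strength < 1.0:
                raise ConfigError(
                    f"planted_cnv_drivers[{g}].coupling_strength: target |r| must "
                    f"be in [0, 1)"
                )
            if spec.cnv_magnitude <= 0:
                raise ConfigError(f"planted_cnv_drivers[{g}].cnv_magnitude: must be > 0")
        for g, spec in self.planted_meth_drivers.items():
            if spec.direction not in ("hyper", "hypo"):
                raise ConfigError(
                    f"planted_meth_drivers[{g}].direction: must be 'hyper' or 'hypo'"
                )
            if not 0.0 < spec.delta_beta < 0.9:
                raise ConfigError(
                    f"planted_meth_drivers[{g}].delta_beta: must be in (0, 0.9)"
                )
            if not 0.0 <= spec.coupling_strength < 1.0:
                raise ConfigError(
                    f"planted_meth_drivers[{g}].coupling_strength: target |r| must "
                    f"be in [0, 1)"
                )
        for g, r in self.mutation_rate_per_gene.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"mutation_rate_per_gene[{g}]: must be in [0, 1]")

    # -- derived -------------------------------------------------------
    @property
    def gene_names(self) -> list:
        filler = [f"GENE{i:04d}" for i in range(self.n_genes - len(self.gene_panel))]
        return list(self.gene_panel) + filler

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed),
                                   spawn_key=(_STREAMS[stream],))
        )


def _coupling_coefficient(target_r: float) -> float:
    return target_r / math.sqrt(1.0 - target_r**2)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(config: CohortConfig) -> tuple[OmicsCohort, pd.DataFrame]:
    """Generate one cohort and its truth table.

    Returns ``(cohort, truth)`` where ``truth`` is a DataFrame indexed
    by gene with columns ``dysregulation`` ({up, down, none}),
    ``driver_mechanism`` ({cnv_gain, cnv_loss, hypermethylation,
    hypomethylation, none}) and ``prognostic`` ({poor, favorable,
    none}). Identical configs (including seed) yield bit-identical
    output.
    """
    config.validate()
    genes = config.gene_names
    code = config.cancer_code
    tumor_ids = [f"{code}-T{i:04d}" for i in range(config.n_tumor)]
    normal_ids = [f"{code}-N{i:04d}" for i in range(config.n_normal)]
    samples = tumor_ids + normal_ids
    n_t, n_n = config.n_tumor, config.n_normal
    gi = {g: k for k, g in enumerate(genes)}

    # --- expression ---------------------------------------------------
    rng_e = config.rng("expression")
    baselines = rng_e.uniform(4.0, 10.0, len(genes))
    expr = baselines[:, None] + rng_e.normal(
        0.0, config.noise_sd, (len(genes), len(samples))
    )
    for g, eff in config.planted_up.items():
        expr[gi[g], :n_t] += abs(eff)
    for g, eff in config.planted_down.items():
        expr[gi[g], :n_t] -= abs(eff)

    # --- CNV (tumor samples only) --------------------------------------
    rng_c = config.rng("cnv")
    cnv = rng_c.normal(0.0, config.cnv_noise_sd, (len(genes), n_t))
    for g, spec in config.planted_cnv_drivers.items():
        k = gi[g]
        altered = rng_c.random(n_t) < spec.alteration_fraction
        sign = 1.0 if spec.direction == "gain" else -1.0
        cnv[k, altered] = rng_c.normal(sign * spec.cnv_magnitude, 0.1, altered.sum())
        c = _coupling_coefficient(spec.coupling_strength)
        expr[k, :n_t] += c * config.noise_sd * _standardize(cnv[k])

    # --- methylation ----------------------------------------------------
    rng_m = config.rng("methylation")
    s = config.beta_logit_sd
    # variance correction for E[sigmoid(N(mu, s^2))] ~= sigmoid(mu / kappa)
    kappa = math.sqrt(1.0 + math.pi * s**2 / 8.0)
    base_beta = rng_m.uniform(0.2, 0.8, len(genes))
    mu = logit(base_beta)[:, None] + rng_m.normal(0.0, s, (len(genes), len(samples)))
    for g, spec in config.planted_meth_drivers.items():
        k = gi[g]
        signed = spec.delta_beta if spec.direction == "hyper" else -spec.delta_beta
        normal_target = np.clip(0.5 - signed / 2.0, 0.05, 0.95)
        tumor_target = np.clip(normal_target + signed, 0.05, 0.95)
        mu[k] = logit(normal_target) * kappa + rng_m.normal(0.0, s, len(samples))
        mu[k, :n_t] += (logit(tumor_target) - logit(normal_target)) * kappa
    beta = expit(mu)
    for g, spec in config.planted_meth_drivers.items():
        k = gi[g]
        c = _coupling_coefficient(spec.coupling_strength)
        expr[k, :n_t] -= c * config.noise_sd * _standardize(beta[k, :n_t])

    # --- survival (tumor samples) ---------------------------------------
    rng_s = config.rng("survival")
    lp = np.zeros(n_t)
    for g, eff in config.planted_prognostic.items():
        lp += eff * _standardize(expr[gi[g], :n_t])
    u = rng_s.uniform(size=n_t)
    t_event = config.baseline_hazard_scale * (
        -np.log(u) / np.exp(lp)
    ) ** (1.0 / config.baseline_hazard_shape)
    c_time = _censoring_times(
        t_event, config.censoring_rate, config.max_follow_up, rng_s
    )
    os_time = np.minimum(t_event, c_time)
    os_event = (t_event <= c_time).astype(int)

    # --- clinical covariates ---------------------------------------------
    rng_cl = config.rng("clinical")
    t_idx = rng_cl.choice([1, 2, 3, 4], n_t, p=[0.20, 0.35, 0.30, 0.15])
    n_idx = rng_cl.choice([0, 1, 2, 3], n_t, p=[0.45, 0.25, 0.20, 0.10])
    m_idx = rng_cl.choice([0, 1], n_t, p=[0.85, 0.15])
    stage = np.where(
        m_idx == 1, 4,
        np.where((n_idx >= 2) | (t_idx == 4), 3,
                 np.where((n_idx == 1) | (t_idx == 3), 2, 1)),
    )
    gender = rng_cl.choice(["MALE", "FEMALE"], n_t)
    age = np.clip(np.round(rng_cl.normal(63.0, 10.0, n_t)), 25, 90)
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "t_index": t_idx.astype(float),
            "n_index": n_idx.astype(float),
            "m_index": m_idx.astype(float),
            "stage": stage.astype(float),
            "gender": gender,
            "age": age,
        },
        index=pd.Index(tumor_ids, name="sample"),
    )[CLINICAL_COLUMNS]
    if config.missing_clinical_rate > 0:
        for col in ("t_index", "n_index", "m_index", "stage", "gender", "age"):
            drop = rng_cl.random(n_t) < config.missing_clinical_rate
            clinical.loc[drop, col] = np.nan

    # --- mutations ---------------------------------------------------------
    rng_mu = config.rng("mutation")
    maf_rows = []
    classes, vtypes, probs = zip(*_NONSYN_MIX)
    probs = np.asarray(probs) / sum(probs)
    cat_names = list(_SPECTRUM_PRIOR)
    cat_probs = np.asarray(list(_SPECTRUM_PRIOR.values()))
    for g in sorted(config.mutation_rate_per_gene):
        rate = config.mutation_rate_per_gene[g]
        carriers = np.flatnonzero(rng_mu.random(n_t) < rate)
        for ci in carriers:
            j = rng_mu.choice(len(classes), p=probs)
            vclass, vtype = classes[j], vtypes[j]
            if vtype == "SNP":
                cat = cat_names[rng_mu.choice(len(cat_names), p=cat_probs)]
                ref, alt = cat.split(">")
                if rng_mu.random() < 0.5:  # random strand
                    ref, alt = _COMP[ref], _COMP[alt]
            elif vtype == "DEL":
                ref, alt = rng_mu.choice(_NT), "-"
            else:  # INS
                ref, alt = "-", rng_mu.choice(_NT)
            maf_rows.append((g, tumor_ids[ci], vclass, vtype, str(ref), str(alt)))
    mutations = pd.DataFrame(maf_rows, columns=MAF_COLUMNS)

    cohort = OmicsCohort(
        cancer_code=code,
        expression=pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                                columns=samples),
        sample_type=pd.Series(
            [TUMOR] * n_t + [NORMAL] * n_n, index=samples, name="sample_type"
        ),
        cnv=pd.DataFrame(cnv, index=pd.Index(genes, name="gene"),
                         columns=tumor_ids),
        methylation=pd.DataFrame(beta, index=pd.Index(genes, name="gene"),
                                 columns=samples),
        mutations=mutations,
        clinical=clinical,
    )
    truth = _truth_table(config, genes)
    return cohort, truth


def _censoring_times(t_event: np.ndarray, target: float, tau: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Independent exponential censoring, administratively truncated at
    *tau*, with the exponential rate calibrated so the expected
    censoring fraction on this cohort matches *target*."""
    t = np.asarray(t_event, dtype=float)
    admin = float(np.mean(t > tau))

    def frac_censored(rate: float) -> float:
        return float(np.mean(np.where(t > tau, 1.0, 1.0 - np.exp(-rate * np.minimum(t, tau)))))

    if target <= admin or target <= 0:
        rate = 0.0
    elif target >= 1.0:
        rate = np.inf
    else:
        hi = 1.0
        while frac_censored(hi) < target and hi < 1e8:
            hi *= 10.0
        rate = brentq(lambda r: frac_censored(r) - target, 0.0, hi, xtol=1e-12)
    if rate == 0.0:
        c = np.full_like(t, np.inf)
    elif np.isinf(rate):
        c = np.zeros_like(t)
    else:
        c = rng.exponential(1.0 / rate, size=t.shape)
    return np.minimum(c, tau)


def _truth_table(config: CohortConfig, genes: list) -> pd.DataFrame:
    truth = pd.DataFrame(
        {
            "dysregulation": "none",
            "driver_mechanism": "none",
            "prognostic": "none",
        },
        index=pd.Index(genes, name="gene"),
    )
    truth.loc[list(config.planted_up), "dysregulation"] = "up"
    truth.loc[list(config.planted_down), "dysregulation"] = "down"
    for g, spec in config.planted_cnv_drivers.items():
        truth.loc[g, "driver_mechanism"] = (
            "cnv_gain" if spec.direction == "gain" else "cnv_loss"
        )
    for g, spec in config.planted_meth_drivers.items():
        truth.loc[g, "driver_mechanism"] = (
            "hypermethylation" if spec.direction == "hyper" else "hypomethylation"
        )
    for g, eff in config.planted_prognostic.items():
        if eff > 0:
            truth.loc[g, "prognostic"] = "poor"
        elif eff < 0:
            truth.loc[g, "prognostic"] = "favorable"
    return truth


def generate_pan_cancer(
    configs: list[CohortConfig],
) -> list[tuple[OmicsCohort, pd.DataFrame]]:
    """Generate independent cohorts for a list of configs.

    Cohorts are seeded from their own configs, so the output for a
    given cancer code is invariant to the order of *configs*.
    """
    if not configs:
        raise ConfigError("configs: need at least one cohort configuration")
    codes = [c.cancer_code for c in configs]
    if len(set(codes)) != len(codes):
        dups = sorted({c for c in codes if codes.count(c) > 1})
        raise ConfigError(f"cancer_code: duplicate codes {dups}")
    return [generate_cohort(c) for c in configs]
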