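"""End-to-end pan-cancer orchestration.

``run_pan_cancer`` executes, per cohort: the differential-expression
screen, gene-set enrichment of the ITG panel against the cohort's full
gene universe, CNV and methylation driver screens, the mutation
summary, the survival cutpoint scan at the total/10-year/5-year
horizons, the prognostic-dysregulated intersection, a Cox risk model
over those genes plus TNM indexes, and the clinical-association screen;
then cross-cancer Jaccard connectivity of the up- and down-regulated
sets. Stages whose required omic is missing are skipped with a logged
reason. All tables plus a manifest are written with
:func:`panitg.io.write_results`; identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clinical_mod
from . import drivers as drivers_mod
from . import expression as expr_mod
from . import mutations as mut_mod
from . import survival as surv_mod
from .cohort import OmicsCohort
from .genes import ITG_PANEL
from .io import read_cohort, write_results
from .risk import CoxRiskModel
from .synthetic import CnvDriverSpec, CohortConfig, MethDriverSpec, generate_cohort

log = logging.getLogger("panitg")

__all__ = [
    "RunConfig",
    "load_run_config",
    "default_run_config",
    "validate_config",
    "run_pan_cancer",
]


@dataclass
class RunConfig:
    """Thresholds and inputs for one pan-cancer run.

    Threshold defaults are the published criteria: DE FDR < 0.05 with
    |log2FC| >= 1; CNV alteration cut 0.1, altered fraction 0.4, mean
    |CNV| 0.1, r > 0.3; |delta beta| > 0.05 with r < -0.3; FDR 0.05
    throughout; cutpoint scan between the 10th and 90th percentiles;
    horizons total/120/60 months; risk split at the median.
    """

    cohorts: list = field(default_factory=list)       # CohortConfig objects
    cohort_dirs: list = field(default_factory=list)   # or on-disk bundles
    gene_panel: tuple = tuple(ITG_PANEL)
    de_fdr: float = 0.05
    de_log2fc: float = 1.0
    driver_thresholds: drivers_mod.DriverThresholds = field(
        default_factory=drivers_mod.DriverThresholds
    )
    survival_lower_pct: float = 0.10
    survival_upper_pct: float = 0.90
    survival_alpha: float = 0.05
    horizons: dict = field(
        default_factory=lambda: dict(surv_mod.HORIZONS)
    )
    risk_split_percentile: float = 50.0
    n_perm: int = 1000
    age_cut: float | None = None
    seed: int = 0

    def effective_cohort_seed(self, cohort_seed: int) -> int:
        return int((self.seed * 1000003 + cohort_seed) % (2**31))


def validate_config(cfg: RunConfig) -> list[str]:
    """Aggregate configuration problems (empty list = valid)."""
    issues = []
    if not cfg.cohorts and not cfg.cohort_dirs:
        issues.append("cohorts: at least one cohort (synthetic or on-disk) required")
    if cfg.n_perm < 10:
        issues.append(f"n_perm: must be >= 10 (got {cfg.n_perm})")
    if not 0 <= cfg.survival_lower_pct < cfg.survival_upper_pct <= 1:
        issues.append(
            f"survival_lower_pct/survival_upper_pct: need "
            f"0 <= lower < upper <= 1 (got {cfg.survival_lower_pct}, "
            f"{cfg.survival_upper_pct})"
        )
    if not 0 < cfg.risk_split_percentile < 100:
        issues.append("risk_split_percentile: must be in (0, 100)")
    for name in ("de_fdr", "survival_alpha"):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            issues.append(f"{name}: must be in (0, 1) (got {v})")
    if cfg.de_log2fc < 0:
        issues.append("de_log2fc: must be >= 0")
    codes = [c.cancer_code for c in cfg.cohorts]
    if len(set(codes)) != len(codes):
        issues.append("cohorts: duplicate cancer codes")
    for c in cfg.cohorts:
        try:
            c.validate()
        except Exception as exc:  # noqa: BLE001 - aggregate, don't raise
            issues.append(f"cohort {c.cancer_code}: {exc}")
    return issues


# --------------------------------------------------------------------------
# Config file handling
# --------------------------------------------------------------------------

def _cohort_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key, spec_cls in (("planted_cnv_drivers", CnvDriverSpec),
                          ("planted_meth_drivers", MethDriverSpec)):
        raw = d.get(key) or {}
        d[key] = {
            g: spec_cls(**v) if isinstance(v, dict) else spec_cls(*v)
            for g, v in raw.items()
        }
    for key in ("planted_up", "planted_down", "planted_prognostic",
                "mutation_rate_per_gene"):
        d[key] = d.get(key) or {}
    if d.get("gene_panel") is None:
        d["gene_panel"] = tuple(ITG_PANEL)
    return CohortConfig(**d)


def load_run_config(path_or_text) -> tuple[RunConfig, str]:
    """Parse a YAML run config; returns (config, raw text) — the text is
    hashed into the run manifest."""
    s = str(path_or_text)
    text = Path(s).read_text() if "\n" not in s and Path(s).exists() else s
    raw = yaml.safe_load(text)
    thr = raw.get("thresholds", {}) or {}
    driver_kwargs = {
        k: thr[k]
        for k in ("cnv_alteration_cut", "cnv_fraction", "cnv_mean", "cnv_corr",
                  "delta_beta", "meth_corr", "fdr")
        if k in thr
    }
    cfg = RunConfig(
        cohorts=[_cohort_from_dict(c) for c in raw.get("cohorts", [])],
        cohort_dirs=[Path(d) for d in raw.get("cohort_dirs", [])],
        gene_panel=tuple(raw.get("gene_panel") or ITG_PANEL),
        de_fdr=thr.get("de_fdr", 0.05),
        de_log2fc=thr.get("de_log2fc", 1.0),
        driver_thresholds=drivers_mod.DriverThresholds(**driver_kwargs),
        survival_lower_pct=thr.get("survival_lower_pct", 0.10),
        survival_upper_pct=thr.get("survival_upper_pct", 0.90),
        survival_alpha=thr.get("survival_alpha", 0.05),
        risk_split_percentile=thr.get("risk_split_percentile", 50.0),
        n_perm=int(raw.get("n_perm", 1000)),
        age_cut=raw.get("age_cut"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg, text


def default_run_config(seed: int = 0) -> tuple[RunConfig, str]:
    """The bundled three-cancer synthetic run configuration."""
    text = (
        resources.files("panitg").joinpath("data/default_run.yaml").read_text()
    )
    cfg, text = load_run_config(text)
    cfg.seed = seed
    return cfg, text


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _empty(columns) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def run_pan_cancer(cfg: RunConfig, out_dir=None,
                   config_text: str | None = None) -> dict:
    """Execute every stage for every cohort; returns the result bundle
    (a dict of DataFrames) and writes it when *out_dir* is given."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid run configuration:\n  " + "\n  ".join(issues))

    cohorts: list[tuple[OmicsCohort, pd.DataFrame | None]] = []
    for cc in cfg.cohorts:
        eff_seed = cfg.effective_cohort_seed(cc.seed)
        cc2 = CohortConfig(**{**cc.__dict__, "seed": eff_seed})
        cohort, truth = generate_cohort(cc2)
        cohorts.append((cohort, truth))
        log.info("generated cohort %s: %d tumor / %d normal / %d genes",
                 cohort.cancer_code, len(cohort.tumor_samples),
                 len(cohort.normal_samples), len(cohort.genes))
    for d in cfg.cohort_dirs:
        code = Path(d).name
        cohorts.append((read_cohort(d, code), None))
        log.info("loaded cohort %s from %s", code, d)

    panel = [g for g in cfg.gene_panel]
    de_all, enrich_rows, cnv_all, meth_all = [], [], [], []
    mut_rate_rows, spectrum_rows = [], []
    surv_all, prog_all, riskmodel_rows, assoc_all, truth_all = [], [], [], [], []

    for cohort, truth in cohorts:
        code = cohort.cancer_code
        panel_here = [g for g in panel if g in cohort.genes]
        if truth is not None:
            truth_all.append(truth.assign(cancer_code=code).reset_index())

        # differential expression over the panel
        de = expr_mod.differential_expression(
            cohort, genes=panel_here, fdr_threshold=cfg.de_fdr,
            log2fc_threshold=cfg.de_log2fc,
        )
        de_all.append(de)
        log.info("%s: DE screen — %d up, %d down", code,
                 (de.direction == "up").sum(), (de.direction == "down").sum())

        # panel enrichment against the cohort's full gene universe
        if len(cohort.genes) > len(panel_here):
            er = expr_mod.enrichment_test(
                cohort, panel_here, n_perm=cfg.n_perm,
                seed=cfg.effective_cohort_seed(zlib.crc32(code.encode()) % 10000),
                set_name="ITG_panel",
            )
            enrich_rows.append(
                {"cancer_code": code, "set_name": er.set_name, "es": er.es,
                 "nes": er.nes, "perm_p": er.perm_p, "n_perm": er.n_perm}
            )
        else:
            log.info("%s: enrichment skipped (no background genes beyond the panel)",
                     code)

        # driver screens
        if cohort.cnv is not None:
            cnv_all.append(drivers_mod.cnv_driver_screen(
                cohort, genes=[g for g in panel_here if g in cohort.cnv.index],
                thresholds=cfg.driver_thresholds, report_all=True,
            ))
        else:
            log.info("%s: CNV driver screen skipped (no CNV matrix)", code)
        if cohort.methylation is not None:
            meth_all.append(drivers_mod.methylation_driver_screen(
                cohort,
                genes=[g for g in panel_here if g in cohort.methylation.index],
                thresholds=cfg.driver_thresholds, report_all=True,
            ))
        else:
            log.info("%s: methylation driver screen skipped (no beta matrix)", code)

        # mutation landscape (denominator: tumor samples with mutation data,
        # i.e. all tumor samples for generated cohorts)
        if cohort.mutations is not None:
            recs = mut_mod.filter_nonsynonymous(cohort.mutations)
            summary = mut_mod.mutation_rates(
                recs, panel_here, list(cohort.tumor_samples), cancer_code=code
            )
            mut_rate_rows.append(
                summary.per_gene_rate.rename_axis("gene").reset_index().assign(
                    cancer_code=code, cohort_rate=summary.cohort_rate
                )
            )
            spectrum_rows.append(
                summary.spectrum.rename_axis("category").reset_index().assign(
                    cancer_code=code
                )
            )
        else:
            log.info("%s: mutation summary skipped (no MAF records)", code)

        # survival screen + prognostic intersection + risk model
        if cohort.clinical is not None:
            sv = surv_mod.survival_screen(
                cohort, genes=panel_here, horizons=cfg.horizons,
                lower_pct=cfg.survival_lower_pct,
                upper_pct=cfg.survival_upper_pct, alpha=cfg.survival_alpha,
            )
            surv_all.append(sv)
            prog = surv_mod.prognostic_dysregulated(de, sv)
            prog_all.append(prog)
            log.info("%s: survival screen — %d prognostic-dysregulated genes",
                     code, len(prog))
            if len(prog):
                try:
                    results = CoxRiskModel.from_cohort(
                        cohort, list(prog.gene), use_tnm=True
                    ).fit()
                    strat = results.stratify(
                        split_percentile=cfg.risk_split_percentile
                    )
                    auc = results.auc(horizon_months=60.0)
                    summ = results.summary().rename_axis("covariate").reset_index()
                    summ.insert(0, "cancer_code", code)
                    summ["km_logrank_p"] = strat["logrank_p"]
                    summ["auc_5yr"] = auc
                    riskmodel_rows.append(summ)
                    log.info("%s: risk model — AUC(5yr)=%.3f, KM log-rank p=%.3g",
                             code, auc, strat["logrank_p"])
                except Exception as exc:  # noqa: BLE001 - stage isolation
                    log.warning("%s: risk model skipped (%s)", code, exc)
            # clinical associations
            assoc_all.append(clinical_mod.clinical_association_screen(
                cohort, genes=panel_here, age_cut=cfg.age_cut
            ))
        else:
            log.info("%s: survival/risk/association stages skipped (no clinical "
                     "table)", code)

    # cross-cancer connectivity
    de_table = pd.concat(de_all, ignore_index=True) if de_all else _empty(
        ["gene", "cancer_code", "log2fc", "p_value", "fdr", "direction"])
    conn_frames = []
    if len(cohorts) >= 2:
        for direction in ("up", "down"):
            sets = {
                code: set(grp.gene[grp.direction == direction])
                for code, grp in de_table.groupby("cancer_code")
            }
            mat, order = expr_mod.connectivity_matrix(sets)
            frame = mat.rename_axis("cancer_code").reset_index()
            frame.insert(0, "direction", direction)
            frame["leaf_order"] = ",".join(order)
            conn_frames.append(frame)

    drivers_frames = cnv_all + meth_all
    drivers_table = (
        pd.concat(drivers_frames, ignore_index=True) if drivers_frames
        else _empty(["gene", "cancer_code", "mechanism"])
    )
    if len(drivers_table) and len(de_table):
        drivers_table = drivers_mod.annotate_concordance(drivers_table, de_table)

    bundle = {
        "dysregulation": de_table,
        "enrichment": pd.DataFrame(enrich_rows),
        "drivers": drivers_table,
        "mutation_rates": (
            pd.concat(mut_rate_rows, ignore_index=True) if mut_rate_rows
            else _empty(["gene", "mutation_rate", "cancer_code", "cohort_rate"])
        ),
        "mutation_spectrum": (
            pd.concat(spectrum_rows, ignore_index=True) if spectrum_rows
            else _empty(["category", "fraction", "cancer_code"])
        ),
        "survival_calls": (
            pd.concat(surv_all, ignore_index=True) if surv_all
            else _empty(["gene", "cancer_code", "horizon", "cut_value",
                         "cut_percentile", "hr", "logrank_p", "label",
                         "final_label"])
        ),
        "prognostic_dysregulated": (
            pd.concat(prog_all, ignore_index=True) if prog_all
            else _empty(["cancer_code", "gene", "direction", "final_label",
                         "hr", "logrank_p", "concordant"])
        ),
        "risk_model": (
            pd.concat(riskmodel_rows, ignore_index=True) if riskmodel_rows
            else _empty(["cancer_code", "covariate", "coef", "hr", "se", "p",
                         "ci_low", "ci_high", "km_logrank_p", "auc_5yr"])
        ),
        "clinical_associations": (
            pd.concat(assoc_all, ignore_index=True) if assoc_all
            else _empty(["gene", "cancer_code", "covariate", "effect",
                         "p_value", "fdr"])
        ),
        "connectivity": (
            pd.concat(conn_frames, ignore_index=True) if conn_frames
            else _empty(["direction", "cancer_code"])
        ),
        "truth": (
            pd.concat(truth_all, ignore_index=True) if truth_all
            else _empty(["gene", "dysregulation", "driver_mechanism",
                         "prognostic", "cancer_code"])
        ),
    }
    if out_dir is not None:
        write_results(bundle, out_dir, seed=cfg.seed, config_text=config_text)
    return bundle
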