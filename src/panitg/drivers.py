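"""CNV- and methylation-driven dysregulation calling.

A gene is called copy-number driven in a cancer when (1) more than 40%
of tumor samples carry CNV > 0.1 (gain) or < -0.1 (loss) while fewer
than 40% carry the opposite alteration, (2) the mean tumor CNV exceeds
|0.1| in the matching direction, and (3) the Pearson correlation between
tumor expression and CNV exceeds 0.3 with BH FDR < 0.05 across the
genes screened in that cancer. Methylation-driven calls require a
tumor-normal mean beta difference |delta beta| > 0.05 that is itself
significant (Mann-Whitney, BH FDR < 0.05) together with a
beta-expression Pearson correlation < -0.3 (FDR < 0.05) over tumor
samples: hypermethylation (delta beta > 0) is the expected driver of
downregulation, hypomethylation of upregulation. All comparisons are
strict inequalities, and the two CNV branches are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OmicsCohort
from .expression import bh_fdr

__all__ = [
    "DriverThresholds",
    "pearson_with_p",
    "cnv_driver_screen",
    "methylation_driver_screen",
    "call_cnv_driver",
    "call_methylation_driver",
    "driver_summary",
]


@dataclass(frozen=True)
class DriverThresholds:
    """Composite driver-calling criteria (defaults as published)."""

    cnv_alteration_cut: float = 0.1   # per-sample |CNV| defining an alteration
    cnv_fraction: float = 0.4         # altered-fraction requirement
    cnv_mean: float = 0.1             # |mean tumor CNV| requirement
    cnv_corr: float = 0.3             # expression-CNV Pearson r requirement
    delta_beta: float = 0.05          # |mean tumor beta - mean normal beta|
    meth_corr: float = -0.3           # expression-beta Pearson r requirement
    fdr: float = 0.05


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-transform p-value
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    return pearson_with_p(x, y)


def cnv_driver_screen(
    cohort: OmicsCohort,
    genes=None,
    thresholds: DriverThresholds = DriverThresholds(),
    report_all: bool = False,
) -> pd.DataFrame:
    """Screen a gene panel for CNV-driven dysregulation.

    The correlation FDR is BH-adjusted across all genes screened in
    this cancer. With ``report_all`` every candidate row is returned
    (mechanism empty where the criteria fail); otherwise only calls.
    """
    if cohort.cnv is None:
        raise ValueError(f"{cohort.cancer_code}: no CNV matrix available")
    tumor = [s for s in cohort.tumor_samples if s in cohort.cnv.columns]
    if len(tumor) < 10:
        raise ValueError(
            f"{cohort.cancer_code}: need >= 10 tumor samples with CNV "
            f"(got {len(tumor)})"
        )
    if genes is None:
        genes = [g for g in cohort.genes if g in cohort.cnv.index]
    cnv = cohort.cnv.loc[genes, tumor].to_numpy(dtype=float)
    expr = cohort.expression.loc[genes, tumor].to_numpy(dtype=float)
    cut = thresholds.cnv_alteration_cut

    frac_gain = (cnv > cut).mean(axis=1)
    frac_loss = (cnv < -cut).mean(axis=1)
    mean_cnv = cnv.mean(axis=1)
    rp = np.array([_safe_pearson(cnv[i], expr[i]) for i in range(len(genes))])
    r, p = rp[:, 0], rp[:, 1]
    fdr = np.full(len(genes), np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = bh_fdr(p[ok])

    corr_ok = (r > thresholds.cnv_corr) & (fdr < thresholds.fdr)
    gain = (
        (frac_gain > thresholds.cnv_fraction)
        & (frac_loss < thresholds.cnv_fraction)
        & (mean_cnv > thresholds.cnv_mean)
        & corr_ok
    )
    loss = (
        (frac_loss > thresholds.cnv_fraction)
        & (frac_gain < thresholds.cnv_fraction)
        & (mean_cnv < -thresholds.cnv_mean)
        & corr_ok
    )
    mechanism = np.where(gain, "cnv_gain", np.where(loss, "cnv_loss", ""))
    out = pd.DataFrame(
        {
            "gene": genes,
            "cancer_code": cohort.cancer_code,
            "mechanism": mechanism,
            "frac_altered": np.where(mean_cnv >= 0, frac_gain, frac_loss),
            "mean_cnv": mean_cnv,
            "pearson_r": r,
            "corr_p": p,
            "corr_fdr": fdr,
        }
    )
    return out if report_all else out[out.mechanism != ""].reset_index(drop=True)


def methylation_driver_screen(
    cohort: OmicsCohort,
    genes=None,
    thresholds: DriverThresholds = DriverThresholds(),
    report_all: bool = False,
) -> pd.DataFrame:
    """Screen a gene panel for methylation-driven dysregulation.

    delta_beta = mean tumor beta - mean normal beta; its significance
    (Mann-Whitney) and the beta-expression correlation (tumor samples)
    are each BH-adjusted across the screened genes.
    """
    if cohort.methylation is None:
        raise ValueError(f"{cohort.cancer_code}: no methylation matrix available")
    meth = cohort.methylation
    tumor = [s for s in cohort.tumor_samples if s in meth.columns]
    normal = [s for s in cohort.normal_samples if s in meth.columns]
    if len(normal) < 3:
        raise ValueError(
            f"{cohort.cancer_code}: delta-beta undefined, need >= 3 normal "
            f"samples with methylation (got {len(normal)})"
        )
    if len(tumor) < 3:
        raise ValueError(f"{cohort.cancer_code}: need >= 3 tumor samples with methylation")
    if genes is None:
        genes = [g for g in cohort.genes if g in meth.index]
    bt = meth.loc[genes, tumor].to_numpy(dtype=float)
    bn = meth.loc[genes, normal].to_numpy(dtype=float)
    expr = cohort.expression.loc[genes, tumor].to_numpy(dtype=float)

    delta = bt.mean(axis=1) - bn.mean(axis=1)
    diff_p = np.asarray(
        stats.mannwhitneyu(bt, bn, axis=1, alternative="two-sided").pvalue,
        dtype=float,
    )
    diff_fdr = bh_fdr(diff_p)
    rp = np.array([_safe_pearson(bt[i], expr[i]) for i in range(len(genes))])
    r, p = rp[:, 0], rp[:, 1]
    corr_fdr = np.full(len(genes), np.nan)
    ok = np.isfinite(p)
    if ok.any():
        corr_fdr[ok] = bh_fdr(p[ok])

    passes = (
        (np.abs(delta) > thresholds.delta_beta)
        & (diff_fdr < thresholds.fdr)
        & (r < thresholds.meth_corr)
        & (corr_fdr < thresholds.fdr)
    )
    mechanism = np.where(
        passes, np.where(delta > 0, "hypermethylation", "hypomethylation"), ""
    )
    out = pd.DataFrame(
        {
            "gene": genes,
            "cancer_code": cohort.cancer_code,
            "mechanism": mechanism,
            "delta_beta": delta,
            "meth_diff_p": diff_p,
            "meth_diff_fdr": diff_fdr,
            "pearson_r": r,
            "corr_p": p,
            "corr_fdr": corr_fdr,
        }
    )
    return out if report_all else out[out.mechanism != ""].reset_index(drop=True)


def call_cnv_driver(
    cohort: OmicsCohort, gene: str,
    thresholds: DriverThresholds = DriverThresholds(),
) -> pd.Series | None:
    """CNV-driver call for one gene (FDR context: all screenable genes
    in the cohort). Returns the call row, or None when the composite
    criteria fail."""
    table = cnv_driver_screen(cohort, thresholds=thresholds, report_all=True)
    row = table[table.gene == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not screenable (missing from CNV/expression)")
    row = row.iloc[0]
    return row if row.mechanism else None


def call_methylation_driver(
    cohort: OmicsCohort, gene: str,
    thresholds: DriverThresholds = DriverThresholds(),
) -> pd.Series | None:
    """Methylation-driver call for one gene (FDR context: all
    screenable genes in the cohort)."""
    table = methylation_driver_screen(cohort, thresholds=thresholds, report_all=True)
    row = table[table.gene == gene]
    if row.empty:
        raise KeyError(
            f"gene {gene!r} not screenable (missing from methylation/expression)"
        )
    row = row.iloc[0]
    return row if row.mechanism else None


def driver_summary(calls: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Counts of driver calls per cancer and per gene x mechanism.

    *calls* is a concatenation of screen outputs (only rows with a
    non-empty mechanism are counted). Returns ``(per_cancer,
    per_gene_mechanism)``.
    """
    if calls is None or calls.empty:
        empty = pd.Series(dtype=int, name="n_driver_genes")
        return empty, pd.DataFrame(columns=["gene", "mechanism", "n_cancers"])
    hits = calls[calls.mechanism != ""]
    per_cancer = hits.groupby("cancer_code").size().rename("n_driver_genes")
    per_gene = (
        hits.groupby(["gene", "mechanism"]).size().rename("n_cancers").reset_index()
    )
    return per_cancer, per_gene


def annotate_concordance(driver_calls: pd.DataFrame,
                         de_calls: pd.DataFrame) -> pd.DataFrame:
    """Flag driver calls whose gene is also dysregulated in the
    mechanism-concordant direction (gain/hypomethylation with "up",
    loss/hypermethylation with "down"). Annotation only; calls are not
    filtered."""
    expected = {
        "cnv_gain": "up",
        "hypomethylation": "up",
        "cnv_loss": "down",
        "hypermethylation": "down",
    }
    de_dir = de_calls.set_index(["cancer_code", "gene"])["direction"]
    out = driver_calls.copy()
    keys = list(zip(out.cancer_code, out.gene))
    observed = [de_dir.get(k, "ns") for k in keys]
    out["dysregulation_direction"] = observed
    out["concordant_dysregulation"] = [
        obs == expected.get(mech, None)
        for obs, mech in zip(observed, out.mechanism)
    ]
    return out
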