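"""Gene-expression associations with TNM stage, gender and age.

Rank-based measures give every covariate a signed effect on a common
[-1, 1] scale: Spearman correlation for ordinal stage and continuous
age, and the rank-biserial correlation (with a two-sided Mann-Whitney
p) for gender. Positive effects mean higher expression with higher
stage, in the reference gender category, or with older age. BH FDR is
applied across genes within one covariate within one cancer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OmicsCohort
from .expression import bh_fdr

__all__ = [
    "stage_association",
    "gender_association",
    "age_association",
    "clinical_association_screen",
]


def stage_association(expression, stage) -> tuple[float, float] | None:
    """Spearman correlation of expression with ordinal TNM stage.

    Returns ``(effect, p)`` or None (with a warning) when fewer than 3
    distinct stage levels are populated.
    """
    expression = np.asarray(expression, dtype=float)
    stage = np.asarray(stage, dtype=float)
    ok = np.isfinite(stage) & np.isfinite(expression)
    if len(np.unique(stage[ok])) < 3:
        warnings.warn("fewer than 3 stage levels populated; skipped", stacklevel=2)
        return None
    r, p = stats.spearmanr(expression[ok], stage[ok])
    return float(r), float(p)


def gender_association(expression, gender, reference: str = "MALE"):
    """Rank-biserial effect (positive = higher expression in the
    reference gender) with a two-sided Mann-Whitney p.

    Returns ``(effect, p)`` or None when either category has fewer than
    3 samples.
    """
    expression = np.asarray(expression, dtype=float)
    gender = pd.Series(gender).astype(object).to_numpy()
    ok = np.isfinite(expression) & pd.notna(gender)
    expression, gender = expression[ok], gender[ok]
    cats = pd.unique(gender)
    if len(cats) < 2:
        warnings.warn("only one gender category present; skipped", stacklevel=2)
        return None
    ref = expression[gender == reference]
    other = expression[gender != reference]
    if len(ref) < 3 or len(other) < 3:
        warnings.warn("fewer than 3 samples in a gender category; skipped",
                      stacklevel=2)
        return None
    u, p = stats.mannwhitneyu(ref, other, alternative="two-sided")
    effect = 2.0 * u / (len(ref) * len(other)) - 1.0
    return float(effect), float(p)


def age_association(expression, age, age_cut: float | None = None):
    """Spearman correlation of expression with age.

    With *age_cut*, age is dichotomized at the cut and a Mann-Whitney /
    rank-biserial comparison (old vs young) is used instead. Returns
    ``(effect, p)`` or None when fewer than 10 samples have age, or age
    is constant.
    """
    expression = np.asarray(expression, dtype=float)
    age = np.asarray(age, dtype=float)
    ok = np.isfinite(age) & np.isfinite(expression)
    expression, age = expression[ok], age[ok]
    if len(age) < 10:
        warnings.warn("fewer than 10 samples with age; skipped", stacklevel=2)
        return None
    if np.unique(age).size < 2:
        warnings.warn("constant age; skipped", stacklevel=2)
        return None
    if age_cut is not None:
        old = expression[age >= age_cut]
        young = expression[age < age_cut]
        if len(old) < 3 or len(young) < 3:
            warnings.warn("age dichotomy leaves a group < 3; skipped", stacklevel=2)
            return None
        u, p = stats.mannwhitneyu(old, young, alternative="two-sided")
        return float(2.0 * u / (len(old) * len(young)) - 1.0), float(p)
    r, p = stats.spearmanr(expression, age)
    return float(r), float(p)


def clinical_association_screen(
    cohort: OmicsCohort, genes=None, age_cut: float | None = None
) -> pd.DataFrame:
    """Associate every panel gene with stage, gender and age in one
    cancer, BH-adjusted per covariate.

    Returns a tidy table with columns gene, cancer_code, covariate,
    effect, p_value, fdr (rows only for computable associations).
    """
    if cohort.clinical is None:
        raise ValueError(f"{cohort.cancer_code}: no clinical table")
    if genes is None:
        genes = list(cohort.genes)
    clin = cohort.clinical
    ids = [s for s in cohort.tumor_samples if s in clin.index]
    stage = clin.loc[ids, "stage"].to_numpy(dtype=float)
    gender = clin.loc[ids, "gender"]
    age = pd.to_numeric(clin.loc[ids, "age"], errors="coerce").to_numpy(dtype=float)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in genes:
            x = cohort.expression.loc[gene, ids].to_numpy(dtype=float)
            for cov, res in (
                ("stage", stage_association(x, stage)),
                ("gender", gender_association(x, gender)),
                ("age", age_association(x, age, age_cut=age_cut)),
            ):
                if res is not None:
                    rows.append(
                        {"gene": gene, "cancer_code": cohort.cancer_code,
                         "covariate": cov, "effect": res[0], "p_value": res[1]}
                    )
    out = pd.DataFrame(rows, columns=["gene", "cancer_code", "covariate",
                                      "effect", "p_value"])
    out["fdr"] = np.nan
    for cov in ("stage", "gender", "age"):
        m = out.covariate == cov
        if m.any():
            out.loc[m, "fdr"] = bh_fdr(out.loc[m, "p_value"].to_numpy())
    return out
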