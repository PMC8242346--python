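"""Differential-expression screen and Fig-1-style analytics.

Per cancer type: tumor-vs-normal dysregulation calls (two-sided
Mann-Whitney p, Benjamini-Hochberg FDR across the screened panel, a
log2 fold-change magnitude gate), a weighted Kolmogorov-Smirnov gene-set
enrichment score with phenotype-permutation testing, Jaccard-index
connectivity between per-cancer dysregulated sets with average-linkage
clustering, and gene-gene Pearson co-expression matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .cohort import OmicsCohort

__all__ = [
    "bh_fdr",
    "log2_fold_change",
    "differential_expression",
    "enrichment_score",
    "enrichment_test",
    "EnrichmentResult",
    "jaccard_index",
    "connectivity_matrix",
    "coexpression_matrix",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returned in the original input order; each q >= its raw p and the
    sequence is monotone after the step-up enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(expression: pd.DataFrame, tumor_ids, normal_ids,
                     gene: str) -> float:
    """Mean log2(tumor) minus mean log2(normal) for one gene.

    Input expression is assumed to already be on the log2 scale, so the
    difference of group means is the log2 fold change.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    tumor_ids, normal_ids = list(tumor_ids), list(normal_ids)
    if not tumor_ids or not normal_ids:
        raise ValueError("both tumor and normal groups must be non-empty")
    row = expression.loc[gene]
    return float(row[tumor_ids].mean() - row[normal_ids].mean())


def differential_expression(
    cohort: OmicsCohort,
    genes=None,
    fdr_threshold: float = 0.05,
    log2fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Tumor-vs-normal dysregulation calls for a gene panel.

    Two-sided Mann-Whitney test per gene; BH FDR across the screened
    genes within this one cancer. A direction ("up"/"down") is assigned
    only when fdr < *fdr_threshold* AND |log2fc| >= *log2fc_threshold*;
    otherwise the call is "ns".

    Returns a DataFrame with columns gene, cancer_code, log2fc,
    p_value, fdr, direction.
    """
    tumor = list(cohort.tumor_samples)
    normal = list(cohort.normal_samples)
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError(
            f"insufficient data: need >=3 tumor and >=3 normal samples "
            f"(got {len(tumor)} tumor, {len(normal)} normal)"
        )
    if genes is None:
        genes = list(cohort.genes)
    expr = cohort.expression
    t_mat = expr.loc[genes, tumor].to_numpy(dtype=float)
    n_mat = expr.loc[genes, normal].to_numpy(dtype=float)
    res = stats.mannwhitneyu(t_mat, n_mat, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    log2fc = t_mat.mean(axis=1) - n_mat.mean(axis=1)
    fdr = bh_fdr(pvals)
    direction = np.where(
        (fdr < fdr_threshold) & (np.abs(log2fc) >= log2fc_threshold),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "cancer_code": cohort.cancer_code,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )


# --------------------------------------------------------------------------
# Gene-set enrichment (weighted Kolmogorov-Smirnov running sum)
# --------------------------------------------------------------------------

def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, pd.Series]:
    """Weighted KS enrichment score over a ranked gene list.

    *ranked* maps gene -> ranking statistic, ordered from most positive
    to most negative. Hits increment the running sum by
    |statistic|^weight_exponent (normalized over set members); misses
    decrement by 1/(N - Nh). The score is the running sum's maximum
    deviation from zero (signed). Returns ``(es, running_sum)``.
    """
    gene_set = set(gene_set)
    universe = list(ranked.index)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    hits = np.array([g in gene_set for g in universe])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene_set has no members in the ranked universe")
    if n_hit == len(universe):
        raise ValueError(
            "gene_set equals the ranked universe; miss penalty undefined"
        )
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero statistics: fall back to unweighted hits
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hits) / (len(universe) - n_hit)
    running = np.cumsum(steps)
    mx, mn = float(running.max()), float(running.min())
    # the positive deviation wins an (effective) magnitude tie
    es = mx if mx >= -mn - 1e-12 else mn
    return es, pd.Series(running, index=ranked.index, name="running_sum")


def _signal_to_noise(t_mat: np.ndarray, n_mat: np.ndarray,
                     sd_floor_frac: float = 0.1) -> np.ndarray:
    """Per-gene signal-to-noise ranking statistic with SD floors.

    Each group SD is floored at *sd_floor_frac* x |group mean| (and a
    tiny absolute floor) to stabilize near-constant genes.
    """
    mt, mn = t_mat.mean(axis=1), n_mat.mean(axis=1)
    st = np.maximum(t_mat.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(mt), 1e-8))
    sn = np.maximum(n_mat.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(mn), 1e-8))
    return (mt - mn) / (st + sn)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    perm_p: float
    n_perm: int


def enrichment_test(
    cohort: OmicsCohort,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Phenotype-permutation enrichment test of a gene set.

    Genes are ranked by the tumor-vs-normal signal-to-noise ratio; the
    null distribution comes from permuting the tumor/normal labels.
    ``perm_p = (1 + #{|null es| >= |observed es|}) / (1 + n_perm)`` and
    ``nes = es / mean(|null es| of the matching sign)``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    tumor = list(cohort.tumor_samples)
    normal = list(cohort.normal_samples)
    if not tumor or not normal:
        raise ValueError("both phenotypes must be present")
    expr = cohort.expression
    mat = expr[tumor + normal].to_numpy(dtype=float)
    n_t = len(tumor)
    genes = list(expr.index)

    def es_for(matrix: np.ndarray) -> float:
        stat = _signal_to_noise(matrix[:, :n_t], matrix[:, n_t:])
        order = np.argsort(-stat, kind="stable")
        ranked = pd.Series(stat[order], index=[genes[i] for i in order])
        return enrichment_score(ranked, gene_set, weight_exponent)[0]

    observed = es_for(mat)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(mat.shape[1])
        null[i] = es_for(mat[:, perm])
    perm_p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    same_sign = null[np.sign(null) == np.sign(observed)]
    ref = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = observed / ref if ref > 0 else np.nan
    return EnrichmentResult(set_name=set_name, es=observed, nes=float(nes),
                            perm_p=float(perm_p), n_perm=n_perm)


# --------------------------------------------------------------------------
# Connectivity and co-expression
# --------------------------------------------------------------------------

def jaccard_index(set_a, set_b) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def connectivity_matrix(
    dysregulated_sets: dict,
) -> tuple[pd.DataFrame, list]:
    """Pairwise Jaccard matrix of per-cancer dysregulated gene sets,
    plus the leaf order of average-linkage clustering on distance 1-J.

    *dysregulated_sets* maps cancer_code -> set of genes. Returns
    ``(matrix, leaf_order)`` with the matrix in input key order.
    """
    codes = list(dysregulated_sets)
    if len(codes) < 2:
        raise ValueError("connectivity requires >= 2 cancers")
    n = len(codes)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard_index(
                dysregulated_sets[codes[i]], dysregulated_sets[codes[j]]
            )
    dist = squareform(1.0 - mat, checks=False)
    order = [codes[i] for i in leaves_list(average(dist))]
    return pd.DataFrame(mat, index=codes, columns=codes), order


def coexpression_matrix(
    cohort: OmicsCohort, genes=None, samples=None
) -> pd.DataFrame:
    """Gene x gene Pearson correlation over a sample subset.

    Zero-variance genes get NaN rows/columns (diagonal included) with a
    warning rather than an error.
    """
    if genes is None:
        genes = list(cohort.genes)
    if samples is None:
        samples = list(cohort.tumor_samples)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for co-expression")
    mat = cohort.expression.loc[genes, samples].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    if flat.size:
        warnings.warn(
            f"zero-variance gene(s) set to NaN in co-expression: "
            f"{[genes[i] for i in flat]}",
            stacklevel=2,
        )
        corr[flat, :] = np.nan
        corr[:, flat] = np.nan
    else:
        np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)
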