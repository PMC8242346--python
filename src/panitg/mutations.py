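"""Mutation-landscape summaries from MAF-style records.

Nonsynonymous filtering, per-gene and per-cohort mutation rates, the
six-category substitution spectrum (SNVs collapsed to the
pyrimidine-reference frame C>A, C>G, C>T, T>A, T>C, T>G), and a
three-group normal / wild-type tumor / mutant tumor expression
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OmicsCohort

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "SPECTRUM_CATEGORIES",
    "filter_nonsynonymous",
    "classify_substitution",
    "mutation_rates",
    "MutationSummary",
    "expression_by_mutation_status",
]

#: canonical protein-altering variant classes retained by the filter
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: classes known to be non-protein-altering (dropped silently)
_KNOWN_DROPPED = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "lincRNA",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

SPECTRUM_CATEGORIES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def filter_nonsynonymous(records: pd.DataFrame, allowlist=None) -> pd.DataFrame:
    """Retain protein-altering variant classes; drop Silent and
    non-coding classes. Unknown classifications are dropped with a
    warning (override via *allowlist*)."""
    allow = frozenset(allowlist) if allowlist is not None else NONSYNONYMOUS_CLASSES
    cls = records["Variant_Classification"]
    unknown = sorted(set(cls) - set(allow) - _KNOWN_DROPPED)
    if unknown:
        warnings.warn(
            f"unknown variant classifications dropped: {unknown}", stacklevel=2
        )
    return records[cls.isin(allow)].reset_index(drop=True)


def classify_substitution(ref: str, alt: str) -> str:
    """Map a single-nucleotide substitution to one of the six
    pyrimidine-reference categories (purine references are complemented
    on both alleles)."""
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(
            f"cannot classify substitution {ref!r}>{alt!r}: "
            f"alleles must be single unambiguous nucleotides"
        )
    if ref == alt:
        raise ValueError(f"reference and alternate alleles are identical ({ref!r})")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class MutationSummary:
    cancer_code: str
    n_samples: int
    per_gene_rate: pd.Series = field(repr=False)
    cohort_rate: float = 0.0
    spectrum: pd.Series = field(default=None, repr=False)


def mutation_rates(
    records: pd.DataFrame,
    gene_panel,
    samples_with_data,
    cancer_code: str = "",
) -> MutationSummary:
    """Per-gene and cohort mutation rates plus the substitution spectrum.

    *records* should already be filtered to nonsynonymous classes.
    *samples_with_data* is the denominator universe: the samples for
    which mutation calls exist. A record whose sample is outside that
    universe makes the denominator inconsistent and raises.
    Spectrum fractions are computed over single-nucleotide records only.
    """
    samples = list(samples_with_data)
    if len(samples) < 1:
        raise ValueError("need >= 1 sample with mutation data")
    sample_set = set(samples)
    stray = set(records["Tumor_Sample_Barcode"]) - sample_set
    if stray:
        raise ValueError(
            f"records reference samples outside the denominator universe: "
            f"{sorted(stray)[:5]} (inconsistent denominator)"
        )
    n = len(samples)
    panel = list(gene_panel)
    in_panel = records[records["Hugo_Symbol"].isin(set(panel))]
    per_gene = (
        in_panel.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique() / n
    )
    per_gene = per_gene.reindex(panel, fill_value=0.0).rename("mutation_rate")
    cohort_rate = in_panel["Tumor_Sample_Barcode"].nunique() / n

    snv = records[
        (records["Variant_Type"] == "SNP")
        & records["Reference_Allele"].isin(_COMPLEMENT)
        & records["Tumor_Seq_Allele2"].isin(_COMPLEMENT)
        & (records["Reference_Allele"] != records["Tumor_Seq_Allele2"])
    ]
    counts = pd.Series(0.0, index=list(SPECTRUM_CATEGORIES))
    if len(snv):
        cats = [
            classify_substitution(r, a)
            for r, a in zip(snv["Reference_Allele"], snv["Tumor_Seq_Allele2"])
        ]
        vc = pd.Series(cats).value_counts()
        counts = vc.reindex(SPECTRUM_CATEGORIES, fill_value=0).astype(float)
        counts /= counts.sum()
    return MutationSummary(
        cancer_code=cancer_code,
        n_samples=n,
        per_gene_rate=per_gene,
        cohort_rate=float(cohort_rate),
        spectrum=counts.rename("fraction"),
    )


def expression_by_mutation_status(
    cohort: OmicsCohort, gene: str, min_group: int = 3
) -> dict | None:
    """Compare expression across normal / wild-type tumor / mutant tumor.

    Mutant tumors are those with >= 1 (pre-filtered) nonsynonymous
    record for *gene*. Returns a dict with group medians and sizes, the
    Kruskal-Wallis p, pairwise Mann-Whitney p-values, and a
    ``monotone_trend`` flag ("decreasing"/"increasing"/None) set when
    the three medians are strictly ordered. Returns None (with a
    warning) when any group has fewer than *min_group* samples.
    """
    if cohort.mutations is None:
        raise ValueError(f"{cohort.cancer_code}: no mutation records")
    if gene not in cohort.expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    recs = filter_nonsynonymous(cohort.mutations)
    mutant_ids = set(recs.loc[recs["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
    tumor = list(cohort.tumor_samples)
    groups = {
        "normal": list(cohort.normal_samples),
        "wild_type": [s for s in tumor if s not in mutant_ids],
        "mutant": [s for s in tumor if s in mutant_ids],
    }
    sizes = {k: len(v) for k, v in groups.items()}
    if min(sizes.values()) < min_group:
        warnings.warn(
            f"{cohort.cancer_code}/{gene}: group below {min_group} samples "
            f"({sizes}); comparison skipped",
            stacklevel=2,
        )
        return None
    row = cohort.expression.loc[gene]
    values = {k: row[v].to_numpy(dtype=float) for k, v in groups.items()}
    kw_p = float(stats.kruskal(*values.values()).pvalue)
    pairs = {}
    names = list(groups)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = names[i], names[j]
            pairs[f"{a}_vs_{b}"] = float(
                stats.mannwhitneyu(values[a], values[b],
                                   alternative="two-sided").pvalue
            )
    medians = {k: float(np.median(v)) for k, v in values.items()}
    m = [medians["normal"], medians["wild_type"], medians["mutant"]]
    trend = None
    if m[0] > m[1] > m[2]:
        trend = "decreasing"
    elif m[0] < m[1] < m[2]:
        trend = "increasing"
    return {
        "gene": gene,
        "cancer_code": cohort.cancer_code,
        "group_sizes": sizes,
        "group_medians": medians,
        "kruskal_p": kw_p,
        "pairwise_p": pairs,
        "monotone_trend": trend,
    }
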