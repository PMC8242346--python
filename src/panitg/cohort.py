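"""In-memory container for one cancer type's multi-omics cohort.

A cohort bundles a log2 expression matrix (genes x samples) with
tumor/normal labels and, optionally, per-gene copy-number values
(tumor samples only), methylation beta-values, MAF-style mutation
records and a clinical table. All components are pandas objects keyed
by the same sample identifiers; :meth:`OmicsCohort.validate` enforces
the structural invariants and reports samples that appear in an
optional omic but not in the expression matrix ("orphans").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

#: minimal MAF column dialect used throughout the package
MAF_COLUMNS = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]

#: clinical table columns (indexed by sample id)
CLINICAL_COLUMNS = [
    "os_time",
    "os_event",
    "t_index",
    "n_index",
    "m_index",
    "stage",
    "gender",
    "age",
]


class CohortValidationError(ValueError):
    """A cohort component violates a structural invariant."""


@dataclass
class OmicsCohort:
    """One cancer type's aligned expression / CNV / methylation /
    mutation / clinical bundle.

    Parameters
    ----------
    cancer_code
        Short cohort label (e.g. ``"STAD"``).
    expression
        genes x samples matrix of log2 expression values.
    sample_type
        Series mapping sample id -> ``"tumor"`` or ``"normal"``.
    cnv
        genes x samples matrix of continuous per-gene copy-number values
        (segment-mean-like; tumor samples only). Optional.
    methylation
        genes x samples matrix of beta-values in [0, 1]. Optional.
    mutations
        MAF-style DataFrame with at least the columns in
        :data:`MAF_COLUMNS`. Optional.
    clinical
        Per-sample clinical table with the columns in
        :data:`CLINICAL_COLUMNS` (missing values allowed except for
        os_time/os_event). Optional.
    """

    cancer_code: str
    expression: pd.DataFrame
    sample_type: pd.Series
    cnv: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    orphan_samples: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    @property
    def tumor_samples(self) -> pd.Index:
        ids = self.sample_type.index[self.sample_type == TUMOR]
        return self.samples.intersection(ids, sort=False)

    @property
    def normal_samples(self) -> pd.Index:
        ids = self.sample_type.index[self.sample_type == NORMAL]
        return self.samples.intersection(ids, sort=False)

    # -- validation --------------------------------------------------
    def validate(self) -> None:
        expr = self.expression
        if expr.columns.duplicated().any():
            dups = expr.columns[expr.columns.duplicated()].tolist()
            raise CohortValidationError(
                f"duplicate expression sample identifiers: {dups}"
            )
        if expr.index.duplicated().any():
            dups = expr.index[expr.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate gene identifiers: {dups}")
        unlabeled = expr.columns.difference(self.sample_type.index)
        if len(unlabeled):
            raise CohortValidationError(
                f"samples without tumor/normal label: {unlabeled.tolist()}"
            )
        bad = set(self.sample_type.dropna()) - {TUMOR, NORMAL}
        if bad:
            raise CohortValidationError(f"unknown sample_type values: {sorted(bad)}")

        if self.methylation is not None:
            vals = self.methylation.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                gene, sample = self._locate_offender(
                    self.methylation, lambda v: (v < 0) | (v > 1)
                )
                raise CohortValidationError(
                    f"methylation beta-value outside [0, 1] at "
                    f"gene {gene!r}, sample {sample!r}"
                )
        if self.clinical is not None and len(self.clinical):
            t = pd.to_numeric(self.clinical["os_time"], errors="coerce")
            if (t.dropna() < 0).any():
                raise CohortValidationError("negative os_time in clinical table")
            ev = pd.to_numeric(self.clinical["os_event"], errors="coerce").dropna()
            if not ev.isin([0, 1]).all():
                raise CohortValidationError("os_event values must be 0 or 1")

        self.orphan_samples = self._find_orphans()
        for omic, ids in self.orphan_samples.items():
            if ids:
                warnings.warn(
                    f"{self.cancer_code}: {len(ids)} {omic} sample(s) not in "
                    f"expression matrix (orphans): {ids[:5]}...",
                    stacklevel=2,
                )

    @staticmethod
    def _locate_offender(df: pd.DataFrame, mask_fn) -> tuple[str, str]:
        mask = mask_fn(df.to_numpy(dtype=float))
        mask &= np.isfinite(df.to_numpy(dtype=float))
        i, j = np.argwhere(mask)[0]
        return str(df.index[i]), str(df.columns[j])

    def _find_orphans(self) -> dict:
        known = set(self.expression.columns)
        orphans = {}
        if self.cnv is not None:
            orphans["cnv"] = sorted(set(self.cnv.columns) - known)
        if self.methylation is not None:
            orphans["methylation"] = sorted(set(self.methylation.columns) - known)
        if self.clinical is not None:
            orphans["clinical"] = sorted(set(self.clinical.index) - known)
        if self.mutations is not None and len(self.mutations):
            orphans["mutations"] = sorted(
                set(self.mutations["Tumor_Sample_Barcode"]) - known
            )
        return orphans

    # -- convenience -------------------------------------------------
    def restrict_genes(self, panel) -> "OmicsCohort":
        """Return a copy restricted to the genes in *panel* (exact,
        case-sensitive matching; genes absent from the cohort are
        silently dropped from the panel)."""
        keep = [g for g in panel if g in self.expression.index]
        return OmicsCohort(
            cancer_code=self.cancer_code,
            expression=self.expression.loc[keep],
            sample_type=self.sample_type,
            cnv=None if self.cnv is None else self.cnv.loc[
                self.cnv.index.intersection(keep, sort=False)
            ],
            methylation=None if self.methylation is None else self.methylation.loc[
                self.methylation.index.intersection(keep, sort=False)
            ],
            mutations=self.mutations,
            clinical=self.clinical,
        )
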