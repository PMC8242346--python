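"""Flat-file readers and writers for cohort bundles and result tables.

Matrix dialect: tab-separated, first column = gene identifier, header
row = sample identifiers (the common TCGA-derived flat-file layout).
Missing values are written as "NA" and accepted as "NA" or an empty
field on read. Floats are serialized with 17 significant digits so a
write/read round trip is lossless. Gene identifier matching is exact
and case-sensitive.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .cohort import CLINICAL_COLUMNS, MAF_COLUMNS, OmicsCohort

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_maf",
    "write_maf",
    "read_clinical",
    "write_clinical",
    "write_cohort",
    "read_cohort",
    "write_results",
    "read_gmt",
]

_FLOAT_FMT = "%.17g"
_NA = "NA"


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line."""


def _read_table_strict(path, index_name: str) -> pd.DataFrame:
    """Tab-separated table with a mandatory unique first (index) column;
    ragged rows and duplicate identifiers raise with the line number."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, idx = [], []
        seen = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path.name}:{lineno}: expected {ncol} fields, "
                    f"got {len(fields)} (ragged row)"
                )
            key = fields[0]
            if key in seen:
                raise ParseError(
                    f"{path.name}:{lineno}: duplicate {index_name} {key!r} "
                    f"(first seen on line {seen[key]})"
                )
            seen[key] = lineno
            idx.append(key)
            rows.append(fields[1:])
    df = pd.DataFrame(rows, index=pd.Index(idx, name=index_name),
                      columns=header[1:])
    return df.replace({"": None, _NA: None})


def read_matrix(path) -> pd.DataFrame:
    """Genes x samples numeric matrix."""
    df = _read_table_strict(path, "gene")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep=_NA,
              index_label="gene")


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[_NA, ""])
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing MAF columns {missing}")
    return df


def write_maf(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_clinical(path) -> pd.DataFrame:
    df = _read_table_strict(path, "sample")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing clinical columns {missing}")
    for col in CLINICAL_COLUMNS:
        if col != "gender":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep=_NA,
                    index_label="sample")


_FILES = {
    "expression": "expression.tsv",
    "cnv": "cnv.tsv",
    "methylation": "methylation.tsv",
    "mutations": "mutations.maf",
    "clinical": "clinical.tsv",
    "sample_type": "sample_type.tsv",
    "truth": "truth.tsv",
}


def write_cohort(cohort: OmicsCohort, out_dir, truth: pd.DataFrame | None = None
                 ) -> dict:
    """Write a cohort bundle into ``out_dir/<cancer_code>/``; returns
    the path map."""
    base = Path(out_dir) / cohort.cancer_code
    base.mkdir(parents=True, exist_ok=True)
    paths = {"expression": base / _FILES["expression"]}
    write_matrix(cohort.expression, paths["expression"])
    st = cohort.sample_type.rename("sample_type").to_frame()
    st.to_csv(base / _FILES["sample_type"], sep="\t", index_label="sample")
    paths["sample_type"] = base / _FILES["sample_type"]
    if cohort.cnv is not None:
        paths["cnv"] = base / _FILES["cnv"]
        write_matrix(cohort.cnv, paths["cnv"])
    if cohort.methylation is not None:
        paths["methylation"] = base / _FILES["methylation"]
        write_matrix(cohort.methylation, paths["methylation"])
    if cohort.mutations is not None:
        paths["mutations"] = base / _FILES["mutations"]
        write_maf(cohort.mutations, paths["mutations"])
    if cohort.clinical is not None:
        paths["clinical"] = base / _FILES["clinical"]
        write_clinical(cohort.clinical, paths["clinical"])
    if truth is not None:
        paths["truth"] = base / _FILES["truth"]
        truth.to_csv(paths["truth"], sep="\t", index_label="gene")
    return paths


def read_cohort(cohort_dir, cancer_code: str,
                gene_panel=None) -> OmicsCohort:
    """Read a cohort bundle written by :func:`write_cohort`.

    Only the expression matrix and sample-type table are mandatory.
    With *gene_panel*, matrices are restricted to the panel (exact
    matching).
    """
    base = Path(cohort_dir)
    if (base / cancer_code).is_dir():
        base = base / cancer_code
    expr_path = base / _FILES["expression"]
    if not expr_path.exists():
        raise FileNotFoundError(f"expression matrix not found: {expr_path}")
    expression = read_matrix(expr_path)
    st = _read_table_strict(base / _FILES["sample_type"], "sample")
    sample_type = st["sample_type"].astype(str)

    def optional(name, reader):
        p = base / _FILES[name]
        return reader(p) if p.exists() else None

    cohort = OmicsCohort(
        cancer_code=cancer_code,
        expression=expression,
        sample_type=sample_type,
        cnv=optional("cnv", read_matrix),
        methylation=optional("methylation", read_matrix),
        mutations=optional("mutations", read_maf),
        clinical=optional("clinical", read_clinical),
    )
    if gene_panel is not None:
        cohort = cohort.restrict_genes(gene_panel)
    return cohort


def read_gmt(path) -> dict:
    """Gene sets in GMT format: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{Path(path).name}:{lineno}: GMT line needs >= 3 fields"
                )
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_results(bundle: dict, out_dir, seed: int | None = None,
                  config_text: str | None = None) -> dict:
    """Write one tab-separated table per result class plus a run
    manifest (JSON: seed, config hash, table row counts).

    *bundle* maps table name -> DataFrame. The manifest carries no
    timestamps so two runs from the same seed and config are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    manifest = {
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(config_text.encode()).hexdigest()
            if config_text is not None else None
        ),
        "tables": {},
    }
    for name in sorted(bundle):
        df = bundle[name]
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                  na_rep=_NA)
        paths[name] = path
        manifest["tables"][name] = int(len(df))
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
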