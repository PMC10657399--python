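"""Readers and writers for the package's tab-delimited interchange formats.

All tables are plain TSV: a clinical table, a MAF-dialect mutation table
(standard columns plus precomputed database-flag columns), a SEG-dialect
segment table (1-based, end-inclusive coordinates), a gene-level CNV call
table and a gene annotation table.  Readers tolerate extra columns and
report the offending column name on schema failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .annotation import MAF_REQUIRED
from .copy_number import SEG_COLUMNS
from .errors import SchemaError

CLINICAL_REQUIRED = [
    "sample_id",
    "her2_class",
    "ihc_score",
    "er_status",
    "er_percent",
    "purity",
    "specimen_type",
    "panel_version",
]

CNV_REQUIRED = ["sample_id", "gene", "call"]
ANNOTATION_REQUIRED = ["gene", "role", "panel_versions"]


def _read_tsv(path, required, label) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # parse failures carry the pandas row context
        raise SchemaError(f"failed to parse {label} table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table is missing column(s): {', '.join(missing)}")
    return df


def read_clinical(path) -> pd.DataFrame:
    return _read_tsv(path, CLINICAL_REQUIRED, "clinical")


def read_maf(path) -> pd.DataFrame:
    df = _read_tsv(path, MAF_REQUIRED, "MAF")
    df["gnomad_present"] = df["gnomad_present"].astype(bool)
    df["clinvar_present"] = df["clinvar_present"].astype(bool)
    df["cosmic_count"] = df["cosmic_count"].astype(int)
    return df


def read_seg(path) -> pd.DataFrame:
    return _read_tsv(path, SEG_COLUMNS, "SEG")


def read_cnv_calls(path) -> pd.DataFrame:
    return _read_tsv(path, CNV_REQUIRED, "CNV call")


def read_annotations(path) -> pd.DataFrame:
    return _read_tsv(path, ANNOTATION_REQUIRED, "gene annotation")


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_cohort(cohort, outdir) -> dict:
    """Write all cohort tables under ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    paths = {
        "clinical": write_tsv(cohort.clinical, outdir / "clinical.tsv"),
        "variants": write_tsv(cohort.variants, outdir / "variants.maf.tsv"),
        "cnv_calls": write_tsv(cohort.cnv_calls, outdir / "cnv_calls.tsv"),
        "segments": write_tsv(cohort.segments, outdir / "segments.seg.tsv"),
        "annotations": write_tsv(cohort.annotations, outdir / "gene_annotations.tsv"),
        "truth": write_tsv(cohort.truth, outdir / "truth.tsv"),
    }
    return {k: str(v) for k, v in paths.items()}


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path
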