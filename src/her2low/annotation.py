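"""Variant filtering cascade and oncogenicity classification.

Tumor-only panels call germline polymorphisms alongside somatic mutations.
The cascade removes variants flagged as present in the gnomAD or ClinVar
population/clinical databases unless rescued by recurrence in COSMIC
(seen more than once, i.e. count >= 2).  Database membership is consumed as
precomputed boolean/count columns; no live queries are made.

Oncogenicity of a retained mutation is the union of two branches:
an OncoKB-style label in {oncogenic, likely_oncogenic, predicted_oncogenic},
or a loss-of-function class (nonsense, frameshift, splice) in a tumor
suppressor gene.  A copy-number event is oncogenic only as a high
amplification (> 6 copies) of an oncogene or a two-copy deletion of a TSG;
every other CNV is a variant of unknown significance.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

# canonical internal variant classes
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
SPLICE = "splice"
INFRAME_INDEL = "inframe_indel"
SYNONYMOUS = "synonymous"
OTHER = "other"

LOF_CLASSES = frozenset({NONSENSE, FRAMESHIFT, SPLICE})
ONCOGENIC_LABELS = frozenset({"oncogenic", "likely_oncogenic", "predicted_oncogenic"})

ROLE_ONCOGENE = "oncogene"
ROLE_TSG = "TSG"

ALL_PANEL_VERSIONS = frozenset({"v1", "v2", "v3"})

# MAF dialect: Variant_Classification values mapped onto internal classes
MAF_CLASS_MAP = {
    "Missense_Mutation": MISSENSE,
    "Nonsense_Mutation": NONSENSE,
    "Frame_Shift_Del": FRAMESHIFT,
    "Frame_Shift_Ins": FRAMESHIFT,
    "Splice_Site": SPLICE,
    "Splice_Region": SPLICE,
    "In_Frame_Del": INFRAME_INDEL,
    "In_Frame_Ins": INFRAME_INDEL,
    "Silent": SYNONYMOUS,
}

MAF_REQUIRED = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "gnomad_present",
    "clinvar_present",
    "cosmic_count",
]

FLAG_COLUMNS = ["gnomad_present", "clinvar_present", "cosmic_count"]

#: COSMIC occurrence count at which a database-flagged variant is rescued
#: ("more than once" read literally: a count of 1 does not rescue).
COSMIC_RESCUE_MIN = 2

REASON_ONCOKB = "oncokb_label"
REASON_LOF_TSG = "lof_in_tsg"
REASON_NONE = "none"


def normalize_variant_class(values: pd.Series) -> pd.Series:
    """Map MAF-dialect Variant_Classification strings to internal classes."""
    return values.map(lambda v: MAF_CLASS_MAP.get(v, v if v in {
        MISSENSE, NONSENSE, FRAMESHIFT, SPLICE, INFRAME_INDEL, SYNONYMOUS
    } else OTHER))


def _check_flags(variants: pd.DataFrame) -> None:
    missing = [c for c in FLAG_COLUMNS if c not in variants.columns]
    if missing:
        raise SchemaError(
            f"variant table is missing database flag column(s): {', '.join(missing)}"
        )


def germline_retained_mask(variants: pd.DataFrame) -> pd.Series:
    """Boolean mask of variants surviving the germline filter."""
    _check_flags(variants)
    if (variants["cosmic_count"] < 0).any():
        raise SchemaError("cosmic_count must be non-negative")
    clean = ~variants["gnomad_present"].astype(bool) & ~variants[
        "clinvar_present"
    ].astype(bool)
    rescued = variants["cosmic_count"] >= COSMIC_RESCUE_MIN
    return clean | rescued


def filter_germline(variants: pd.DataFrame) -> pd.DataFrame:
    """Remove likely-germline variants.

    A variant is retained iff it is absent from both gnomAD and ClinVar, or
    its COSMIC occurrence count is at least 2 (the rescue clause overrides
    both database flags jointly).  Output rows are a subsequence of the
    input, order preserved; the operation is idempotent.
    """
    return variants[germline_retained_mask(variants)]


def _role_map(annotations: pd.DataFrame) -> dict:
    for col in ("gene", "role"):
        if col not in annotations.columns:
            raise SchemaError(f"annotation table is missing column: {col}")
    return dict(zip(annotations["gene"], annotations["role"]))


def classify_mutation_oncogenic(
    variants: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Attach ``oncogenic`` and ``oncogenic_reason`` columns to mutations.

    Branch 1: OncoKB-style label in {oncogenic, likely_oncogenic,
    predicted_oncogenic}.  Branch 2: loss-of-function class in a TSG.
    Synonymous variants are never oncogenic.  Genes absent from the
    annotation table are classified via the label branch only (warned).
    """
    roles = _role_map(annotations)
    out = variants.copy()
    vclass = normalize_variant_class(out["Variant_Classification"])
    label = out.get("oncokb_label", pd.Series("none", index=out.index))
    label = label.fillna("none").astype(str)

    unknown = sorted(set(out["Hugo_Symbol"]) - set(roles))
    if unknown:
        logger.warning(
            "%d gene(s) absent from annotation table; LOF-in-TSG branch "
            "unavailable for: %s",
            len(unknown),
            ", ".join(unknown[:10]),
        )
    role = out["Hugo_Symbol"].map(roles)

    by_label = label.isin(ONCOGENIC_LABELS)
    by_lof = (role == ROLE_TSG) & vclass.isin(LOF_CLASSES)
    not_syn = vclass != SYNONYMOUS
    out["oncogenic"] = (by_label | by_lof) & not_syn
    reason = pd.Series(REASON_NONE, index=out.index)
    reason[by_lof & not_syn] = REASON_LOF_TSG
    reason[by_label & not_syn] = REASON_ONCOKB  # label branch reported when both fire
    out["oncogenic_reason"] = reason
    return out


CNV_HIGH_AMP = "high_amplification"
CNV_AMP = "amplification"
CNV_SINGLE_DEL = "single_copy_deletion"
CNV_TWO_COPY_DEL = "two_copy_deletion"
CNV_NEUTRAL = "neutral"


def classify_cnv_oncogenic(
    cnv_calls: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Attach an ``oncogenic`` column to gene-level CNV calls.

    Oncogenic iff (oncogene and high amplification) or (TSG and two-copy
    deletion); every other event, and any gene of unknown role, is VUS.
    """
    roles = _role_map(annotations)
    out = cnv_calls.copy()
    role = out["gene"].map(roles)
    out["oncogenic"] = ((role == ROLE_ONCOGENE) & (out["call"] == CNV_HIGH_AMP)) | (
        (role == ROLE_TSG) & (out["call"] == CNV_TWO_COPY_DEL)
    )
    return out


def common_genes(annotations: pd.DataFrame, versions=ALL_PANEL_VERSIONS) -> set:
    """Genes assayed by every listed panel version."""
    if "panel_versions" not in annotations.columns:
        raise SchemaError("annotation table is missing column: panel_versions")
    want = set(versions)
    out = set()
    for gene, pv in zip(annotations["gene"], annotations["panel_versions"]):
        have = {v.strip() for v in str(pv).split(",")}
        if want <= have:
            out.add(gene)
    return out


def restrict_to_common_genes(
    events: pd.DataFrame, annotations: pd.DataFrame, gene_col: str = "Hugo_Symbol"
) -> pd.DataFrame:
    """Keep only events in genes present on all three panel versions."""
    keep = common_genes(annotations)
    return events[events[gene_col].isin(keep)]
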