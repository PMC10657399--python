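"""End-to-end orchestration: annotate -> burden -> copy number -> enrichment
-> stratified statistics -> report, with the study's sensitivity subsets.

The pipeline consumes the five input tables (clinical, MAF-dialect
mutations, gene-level CNV calls, SEG-dialect segments, gene annotations),
applies the requested sample subset, runs every analysis stage, and emits a
bundle of result tables plus a JSON-serializable manifest recording every
threshold, exclusion and per-stage sample count (samples_in =
samples_excluded + samples_analyzed at each stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, burden, copy_number, enrichment, io, report, stratified_stats
from .errors import SchemaError
from .synthetic_data import (
    ER_LOW,
    ER_NEGATIVE,
    ER_POSITIVE,
    HER2_LOW,
    HER2_ZERO,
    Cohort,
)

logger = logging.getLogger(__name__)

SUBSET_MODES = ("all", "metastatic_only", "ihc2_vs_0")

ER_GROUP_POSITIVE = "er_positive"
ER_GROUP_NEGATIVE = "er_negative"


@dataclass
class RunConfig:
    """Thresholds and switches for one pipeline run."""

    subset_mode: str = "all"
    mutation_frequency_threshold: float = enrichment.COMMON_EVENT_THRESHOLD
    hm_fallback_threshold: float = burden.DEFAULT_HM_THRESHOLD
    panel_sizes_mb: dict = field(default_factory=lambda: dict(burden.DEFAULT_PANEL_SIZES_MB))
    copy_count_variant: str = "doubling"
    ll_gate_q: float = enrichment.LL_GATE_Q
    max_iterations: int = enrichment.MAX_ITERATIONS
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> "RunConfig":
        if self.subset_mode not in SUBSET_MODES:
            raise ValueError(
                f"unknown subset mode {self.subset_mode!r}; expected one of {SUBSET_MODES}"
            )
        return self


def er_group(er_status: pd.Series) -> pd.Series:
    """Two-level ER stratification: ER-low merged into ER-positive.

    Unknown/unrecorded ER becomes missing (those samples are excluded from
    stratified analyses and modeling).
    """
    mapping = {
        ER_POSITIVE: ER_GROUP_POSITIVE,
        ER_LOW: ER_GROUP_POSITIVE,
        ER_NEGATIVE: ER_GROUP_NEGATIVE,
    }
    return er_status.map(mapping)


def derive_her2_class(ihc_score: pd.Series, ish_positive: pd.Series | None = None) -> pd.Series:
    """HER2 class from the IHC score: 0 -> HER2-0; 1+ or 2+/ISH-negative ->
    HER2-low.  3+ or ISH-positive samples are HER2-positive and rejected."""
    ihc = ihc_score.astype(str)
    if ish_positive is not None and bool(pd.Series(ish_positive).any()):
        raise SchemaError("HER2-positive samples (ISH-positive) must be excluded upstream")
    if (ihc == "3+").any():
        raise SchemaError("HER2-positive samples (IHC 3+) must be excluded upstream")
    out = pd.Series(pd.NA, index=ihc.index, dtype="object")
    out[ihc == "0"] = HER2_ZERO
    out[ihc.isin(["1+", "2+"])] = HER2_LOW
    return out


def apply_subset(clinical: pd.DataFrame, mode: str) -> pd.DataFrame:
    """The study's sensitivity subsets.

    ``all`` is the identity; ``metastatic_only`` keeps metastatic specimens
    with recorded ER; ``ihc2_vs_0`` keeps IHC 2+ (non-amplified, i.e.
    HER2-low by inclusion) and IHC 0 samples with recorded ER.
    """
    if mode not in SUBSET_MODES:
        raise ValueError(f"unknown subset mode: {mode!r}")
    if mode == "all":
        return clinical
    er_known = er_group(clinical["er_status"]).notna()
    if mode == "metastatic_only":
        return clinical[(clinical["specimen_type"] == "metastasis") & er_known]
    return clinical[clinical["ihc_score"].isin(["2+", "0"]) & er_known]


def _stage(manifest: dict, name: str, n_in: int, n_excluded: int, **extra) -> None:
    entry = {
        "samples_in": int(n_in),
        "samples_excluded": int(n_excluded),
        "samples_analyzed": int(n_in - n_excluded),
        **extra,
    }
    manifest["stages"][name] = entry


def run_full_analysis(cohort: Cohort | dict, config: RunConfig | None = None) -> dict:
    """Run every analysis stage on a cohort and return the report bundle.

    ``cohort`` is either a :class:`~her2low.synthetic_data.Cohort` or a dict
    of DataFrames with keys clinical, variants, cnv_calls, segments,
    annotations.  The bundle maps table names to DataFrames and includes a
    ``manifest`` dict; :func:`write_bundle` serializes it.
    """
    config = (config or RunConfig()).validate()
    if isinstance(cohort, Cohort):
        tables = {
            "clinical": cohort.clinical,
            "variants": cohort.variants,
            "cnv_calls": cohort.cnv_calls,
            "segments": cohort.segments,
            "annotations": cohort.annotations,
        }
    else:
        tables = cohort
    clinical_all = tables["clinical"]
    manifest: dict = {
        "subset_mode": config.subset_mode,
        "seed": config.seed,
        "thresholds": {
            "mutation_frequency": config.mutation_frequency_threshold,
            "hm_fallback": config.hm_fallback_threshold,
            "copy_count_bins": [copy_number.DELETION_MAX, copy_number.GAIN_MIN],
            "ll_gate_q": config.ll_gate_q,
            "max_iterations": config.max_iterations,
        },
        "copy_count_variant": config.copy_count_variant,
        "copy_counts_are_relative": True,
        "stages": {},
    }

    # --- subset ------------------------------------------------------------
    clinical = apply_subset(clinical_all, config.subset_mode).copy()
    _stage(manifest, "subset", len(clinical_all), len(clinical_all) - len(clinical))
    keep_ids = set(clinical["sample_id"])
    clinical["er_group"] = er_group(clinical["er_status"])

    # --- annotation: common genes, germline filter, oncogenicity -----------
    variants = tables["variants"]
    variants = variants[variants["Tumor_Sample_Barcode"].isin(keep_ids)]
    n_before_common = len(variants)
    variants = annotation.restrict_to_common_genes(variants, tables["annotations"])
    filtered = annotation.filter_germline(variants)
    classified = annotation.classify_mutation_oncogenic(filtered, tables["annotations"])
    cnv = tables["cnv_calls"]
    cnv = cnv[cnv["sample_id"].isin(keep_ids)]
    cnv = annotation.restrict_to_common_genes(cnv, tables["annotations"], gene_col="gene")
    cnv = annotation.classify_cnv_oncogenic(cnv, tables["annotations"])
    _stage(
        manifest,
        "annotation",
        len(clinical),
        0,
        variants_in=int(n_before_common),
        variants_common_genes=int(len(variants)),
        variants_after_germline_filter=int(len(filtered)),
        variants_oncogenic=int(classified["oncogenic"].sum()),
        cnv_events=int(len(cnv)),
        cnv_oncogenic=int(cnv["oncogenic"].sum()),
    )

    # --- burden -------------------------------------------------------------
    tmb = burden.cohort_tmb(filtered, clinical, config.panel_sizes_mb)
    thr = burden.find_hypermutation_threshold(
        tmb["tmb"], fallback=config.hm_fallback_threshold
    )
    tmb["hypermutated"] = burden.classify_hypermutated(tmb["tmb"], thr.threshold)
    tmb["threshold_used"] = thr.threshold
    cnv_counts = burden.cnv_event_counts(cnv, clinical)
    cnv_cut = burden.find_count_cutoff(cnv_counts.to_numpy())
    _stage(
        manifest,
        "burden",
        len(clinical),
        0,
        hm_threshold=thr.to_dict(),
        n_hypermutated=int(tmb["hypermutated"].sum()),
        cnv_burden_cutoff=cnv_cut.to_dict(),
    )

    # --- copy number ----------------------------------------------------------
    copy_counts = copy_number.estimate_cohort_copy_counts(
        clinical, tables["segments"], variant=config.copy_count_variant
    )
    n_elig = int(copy_counts["eligible"].sum())
    _stage(
        manifest,
        "copy_number",
        len(clinical),
        len(clinical) - n_elig,
        ineligible_reasons=copy_counts.loc[~copy_counts["eligible"], "reason"]
        .value_counts()
        .to_dict(),
    )

    # --- stratified statistics -------------------------------------------------
    cc = copy_counts.merge(
        clinical[["sample_id", "her2_class", "er_group"]], on="sample_id"
    )
    cc_modeled = cc[cc["eligible"] & cc["er_group"].notna()]
    stats_rows = []
    if (
        cc_modeled["her2_class"].nunique() == 2
        and cc_modeled["category"].nunique() >= 2
    ):
        res = stratified_stats.cmh_from_frame(
            cc_modeled, "her2_class", "category", "er_group"
        )
        stats_rows.append({"analysis": "erbb2_copy_category_cmh", **res.to_dict()})
    tmb_m = tmb.merge(
        clinical[["sample_id", "her2_class", "er_group"]], on="sample_id"
    )
    tmb_m = tmb_m[tmb_m["er_group"].notna()]
    if tmb_m["her2_class"].nunique() == 2:
        res = stratified_stats.stratified_kruskal_wallis(
            tmb_m["tmb"], tmb_m["her2_class"], tmb_m["er_group"]
        )
        stats_rows.append({"analysis": "tmb_stratified_kw", **res.to_dict()})
    baseline = stratified_stats.baseline_tests(
        clinical,
        categorical=["er_status", "specimen_type", "panel_version"],
        continuous=["purity"],
    )
    stats_table = pd.DataFrame(stats_rows)
    _stage(manifest, "stratified_stats", len(clinical), len(clinical) - len(tmb_m))

    # --- enrichment ---------------------------------------------------------------
    sample_ids = list(clinical["sample_id"])
    mut_any = enrichment.build_alteration_matrix(filtered, sample_ids)
    mut_onc = enrichment.build_alteration_matrix(
        classified[classified["oncogenic"]], sample_ids
    )
    cnv_onc = enrichment.build_alteration_matrix(
        cnv[cnv["oncogenic"]], sample_ids, gene_col="gene", sample_col="sample_id"
    )
    covariates = pd.DataFrame(
        {
            "her2_low": (clinical["her2_class"] == HER2_LOW).to_numpy(),
            "er_positive": (clinical["er_group"] == ER_GROUP_POSITIVE)
            .astype(float)
            .where(clinical["er_group"].notna(), np.nan)
            .to_numpy(),
            "hypermutated": tmb.set_index("sample_id")
            .reindex(sample_ids)["hypermutated"]
            .to_numpy(),
            "high_cnv_burden": (
                cnv_counts.reindex(sample_ids) > cnv_cut.threshold
            ).to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    enr, enr_manifest = enrichment.run_enrichment(
        {"mutation_any": mut_any, "mutation_oncogenic": mut_onc, "cnv_oncogenic": cnv_onc},
        covariates,
        mutation_threshold=config.mutation_frequency_threshold,
        ll_gate_q=config.ll_gate_q,
        max_iter=config.max_iterations,
    )
    manifest["enrichment"] = enr_manifest
    _stage(
        manifest,
        "enrichment",
        len(clinical),
        int(enr_manifest["samples_excluded_missing_er"]),
    )

    # --- report tables ---------------------------------------------------------------
    freq = report.frequency_table(mut_onc, clinical, by=("her2_class",))
    freq_er = report.frequency_table(mut_onc, clinical, by=("her2_class", "er_group"))
    oncoprint = report.oncoprint_matrix(mut_onc, cnv[cnv["oncogenic"]], clinical)
    cc_summary = report.copy_count_summary(copy_counts, clinical)

    bundle = {
        "clinical": clinical,
        "filtered_variants": classified,
        "cnv_calls": cnv,
        "tmb": tmb,
        "copy_counts": copy_counts,
        "stratified_tests": stats_table,
        "baseline_tests": baseline,
        "enrichment": enr,
        "frequency_by_her2": freq,
        "frequency_by_her2_er": freq_er,
        "oncoprint": oncoprint,
        "copy_count_summary": cc_summary,
        "manifest": manifest,
    }
    _audit_counts(manifest)
    return bundle


def _audit_counts(manifest: dict) -> None:
    """Assert the per-stage counts ledger balances."""
    for name, st in manifest["stages"].items():
        if st["samples_in"] != st["samples_excluded"] + st["samples_analyzed"]:
            raise AssertionError(f"counts ledger does not balance at stage {name}")


def write_bundle(bundle: dict, outdir) -> dict:
    """Serialize a report bundle to TSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    paths = {}
    for name, obj in bundle.items():
        if name == "manifest":
            paths[name] = str(io.write_json(obj, outdir / "manifest.json"))
        elif isinstance(obj, pd.DataFrame):
            paths[name] = str(io.write_tsv(obj, outdir / f"{name}.tsv"))
    return paths


def load_tables(
    clinical_path, maf_path, cnv_path, seg_path, annotation_path
) -> dict:
    """Load the five input tables from disk into a pipeline-ready dict."""
    return {
        "clinical": io.read_clinical(clinical_path),
        "variants": io.read_maf(maf_path),
        "cnv_calls": io.read_cnv_calls(cnv_path),
        "segments": io.read_seg(seg_path),
        "annotations": io.read_annotations(annotation_path),
    }
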