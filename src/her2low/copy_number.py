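"""Purity-corrected relative copy-count estimation for ERBB2.

Tumor-only panel sequencing reports a segment log2 read-depth ratio (log2R)
that is diluted by the normal-cell fraction of the specimen.  Under the
standard two-population contamination model the observed depth ratio of a
segment with tumor copy number ``CN`` in a specimen of tumor purity ``p`` is

    ratio = (p * CN + 2 * (1 - p)) / 2

so the tumor copy count is recovered by the exact algebraic inverse

    CN = (2 * 2**log2R - 2 * (1 - p)) / p

Because there is no matched normal, no ploidy correction is applied and the
outputs are *relative* copy counts (relative to overall tumor ploidy).
Counts are binned into single-copy deletion (< 1.5), no change ([1.5, 2.5])
and allelic gain (> 2.5).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError

# GRCh37 coordinates of the ERBB2 locus on chromosome 17.
ERBB2_REGION = ("17", 37_844_393, 37_884_915)

#: Category bin edges on the calculated-copies scale.
DELETION_MAX = 1.5
GAIN_MIN = 2.5

CATEGORY_DELETION = "single_copy_deletion"
CATEGORY_NEUTRAL = "no_change"
CATEGORY_GAIN = "allelic_gain"

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]


def forward_log2_ratio(copies, purity):
    """Observed segment log2 ratio for true copy number ``copies`` at ``purity``.

    This is the generative direction of the contamination model; it is the
    exact inverse of :func:`estimate_copy_count` (before flooring).
    """
    copies = np.asarray(copies, dtype=float)
    purity = np.asarray(purity, dtype=float)
    return np.log2((purity * copies + 2.0 * (1.0 - purity)) / 2.0)


def estimate_copy_count(log2_ratio, purity, variant: str = "doubling"):
    """Purity-corrected relative copy count from a segment log2 ratio.

    Parameters
    ----------
    log2_ratio
        Segment log2 depth ratio (scalar or array).
    purity
        Tumor purity in (0, 1].
    variant
        ``"doubling"`` (default) uses the observed ratio ``2 * 2**log2R``,
        the exact inverse of the contamination model, and returns 2.0 at
        ``log2R == 0`` for every purity.  ``"plus_one"`` uses
        ``2**log2R + 1`` instead (an alternative literal reading of the
        published expression, kept for comparison); the two agree at
        ``log2R == 0``.

    Returns
    -------
    Copies floored at zero (negative computed values are clipped; callers
    needing the flag should use :func:`estimate_copy_count_flagged`).
    """
    copies, _ = estimate_copy_count_flagged(log2_ratio, purity, variant=variant)
    return copies


def estimate_copy_count_flagged(log2_ratio, purity, variant: str = "doubling"):
    """Like :func:`estimate_copy_count` but also returns a floored-at-zero flag."""
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must lie in (0, 1]")
    if variant == "doubling":
        observed = 2.0 * np.exp2(log2_ratio)
    elif variant == "plus_one":
        observed = np.exp2(log2_ratio) + 1.0
    else:
        raise ValueError(f"unknown formula variant: {variant!r}")
    raw = (observed - 2.0 * (1.0 - purity)) / purity
    floored = raw < 0
    copies = np.maximum(raw, 0.0)
    if copies.ndim == 0:
        return float(copies), bool(floored)
    return copies, floored


def categorize_copy_count(copies):
    """Bin calculated copies into deletion / no-change / gain.

    The neutral band is the closed interval [1.5, 2.5]; a gain requires
    strictly more than 2.5 copies and a single-copy deletion strictly
    fewer than 1.5.
    """
    copies = np.asarray(copies, dtype=float)
    cats = np.select(
        [copies < DELETION_MAX, copies > GAIN_MIN],
        [CATEGORY_DELETION, CATEGORY_GAIN],
        default=CATEGORY_NEUTRAL,
    )
    if cats.ndim == 0:
        return str(cats)
    return pd.Series(cats, dtype="object")


def gene_log2_ratio(segments: pd.DataFrame, region=ERBB2_REGION) -> pd.Series:
    """Per-sample length-weighted mean log2 ratio over a gene region.

    Segment coordinates are 1-based and end-inclusive.  When a gene spans
    multiple segments the overlap-length-weighted mean is used, which is
    deterministic and independent of row order.  Samples with no overlapping
    segment are absent from the result.
    """
    missing = [c for c in SEG_COLUMNS if c not in segments.columns]
    if missing:
        raise SchemaError(f"segment table is missing column(s): {', '.join(missing)}")
    chrom, start, end = region
    seg = segments[segments["chrom"].astype(str) == str(chrom)]
    overlap = np.minimum(seg["end"], end) - np.maximum(seg["start"], start) + 1
    seg = seg.assign(_overlap=overlap)
    seg = seg[seg["_overlap"] > 0]
    if seg.empty:
        return pd.Series(dtype=float, name="log2_ratio")
    weighted = seg.groupby("sample_id").apply(
        lambda g: np.average(g["log2_ratio"], weights=g["_overlap"]),
        include_groups=False,
    )
    weighted.name = "log2_ratio"
    return weighted


REASON_NO_PURITY = "no_purity"
REASON_NO_SEGMENT = "no_segment"
REASON_IHC_NOS = "ihc_nos"


def assess_eligibility(
    clinical: pd.DataFrame, erbb2_log2r: pd.Series
) -> pd.DataFrame:
    """Eligibility of each sample for copy-count comparisons.

    A sample is ineligible if its tumor purity is unrecorded, no copy-number
    segment covers the gene, or its HER2 IHC value was recorded as "Not
    Otherwise Specified" below 2+.  All applicable reasons are reported,
    semicolon-joined.
    """
    for col in ("sample_id", "purity", "ihc_score"):
        if col not in clinical.columns:
            raise SchemaError(f"clinical table is missing column: {col}")
    rows = []
    has_seg = set(erbb2_log2r.index)
    for _, rec in clinical.iterrows():
        reasons = []
        if pd.isna(rec["purity"]):
            reasons.append(REASON_NO_PURITY)
        if rec["sample_id"] not in has_seg:
            reasons.append(REASON_NO_SEGMENT)
        if str(rec["ihc_score"]).upper() == "NOS":
            reasons.append(REASON_IHC_NOS)
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "eligible": not reasons,
                "reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def estimate_cohort_copy_counts(
    clinical: pd.DataFrame,
    segments: pd.DataFrame,
    region=ERBB2_REGION,
    variant: str = "doubling",
) -> pd.DataFrame:
    """Copy-count table for a cohort: eligibility, copies, category per sample.

    Ineligible samples are retained in the output with ``eligible=False``
    and carry no copies or category.
    """
    log2r = gene_log2_ratio(segments, region=region)
    elig = assess_eligibility(clinical, log2r)
    out = clinical[["sample_id", "purity"]].merge(elig, on="sample_id", how="left")
    out["log2_ratio"] = out["sample_id"].map(log2r)
    copies = np.full(len(out), np.nan)
    floored = np.zeros(len(out), dtype=bool)
    ok = out["eligible"].to_numpy(dtype=bool)
    if ok.any():
        c, f = estimate_copy_count_flagged(
            out.loc[ok, "log2_ratio"].to_numpy(),
            out.loc[ok, "purity"].to_numpy(),
            variant=variant,
        )
        copies[ok] = np.atleast_1d(c)
        floored[ok] = np.atleast_1d(f)
    out["copies"] = copies
    out["floored"] = floored
    out["category"] = pd.NA
    out.loc[ok, "category"] = categorize_copy_count(copies[ok]).to_numpy()
    return out


def copy_count_grid(
    cn_values: Iterable[float], purities: Iterable[float], variant: str = "doubling"
) -> pd.DataFrame:
    """Round-trip table estimate(forward(CN, p), p) over a grid, for diagnostics."""
    rows = []
    for cn in cn_values:
        for p in purities:
            l2r = float(forward_log2_ratio(cn, p))
            est = estimate_copy_count(l2r, p, variant=variant)
            rows.append({"cn": cn, "purity": p, "log2_ratio": l2r, "estimate": est})
    return pd.DataFrame(rows)
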