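"""Tumor mutational burden and hypermutation calling.

TMB is the count of germline-filtered mutations (all classes, including
synonymous) divided by the sequenced panel footprint in megabases.
Hypermutated samples are those whose TMB exceeds a cohort-derived inflection
threshold: the boundary of an exact two-segment least-squares *linear* fit
on the sorted log1p(TMB) curve (a slowly rising body line meeting the
rapidly increasing tail line), with a shipped fallback of 15 mut/Mb for
cohorts too small or too flat to segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Shipped fallback hypermutation threshold in mutations/megabase.
DEFAULT_HM_THRESHOLD = 15.0

#: Approximate exonic footprint (Mb) of each targeted-panel version.
#: The assay vendor does not publish exact values; these are configuration
#: defaults and every TMB depends on them.
DEFAULT_PANEL_SIZES_MB = {"v1": 0.75, "v2": 0.83, "v3": 1.32}

MIN_SAMPLES_FOR_SEGMENTATION = 20
MIN_SEGMENT_FRACTION = 0.02


def compute_tmb(n_mutations: int, panel_size_mb: float) -> float:
    """Mutations per megabase: filtered mutation count / panel footprint."""
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    return n_mutations / panel_size_mb


def cohort_tmb(
    filtered_variants: pd.DataFrame,
    clinical: pd.DataFrame,
    panel_sizes_mb: dict | None = None,
) -> pd.DataFrame:
    """Per-sample TMB for a cohort.

    Every clinical sample appears in the output (zero mutations gives
    TMB 0).  The panel footprint is looked up from the sample's panel
    version.
    """
    panel_sizes_mb = panel_sizes_mb or DEFAULT_PANEL_SIZES_MB
    for col in ("sample_id", "panel_version"):
        if col not in clinical.columns:
            raise SchemaError(f"clinical table is missing column: {col}")
    unknown = set(clinical["panel_version"]) - set(panel_sizes_mb)
    if unknown:
        raise SchemaError(
            f"no panel size configured for version(s): {', '.join(sorted(unknown))}"
        )
    counts = filtered_variants.groupby("Tumor_Sample_Barcode").size()
    out = clinical[["sample_id", "panel_version"]].copy()
    out["n_mutations"] = out["sample_id"].map(counts).fillna(0).astype(int)
    out["panel_mb"] = out["panel_version"].map(panel_sizes_mb)
    out["tmb"] = out["n_mutations"] / out["panel_mb"]
    return out


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the hypermutation-threshold scan."""

    threshold: float
    changepoint_index: int | None
    degenerate: bool
    used_fallback: bool
    method: str = "two_segment_linear_least_squares"

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "changepoint_index": self.changepoint_index,
            "degenerate": self.degenerate,
            "used_fallback": self.used_fallback,
            "method": self.method,
        }


def _two_segment_split(y: np.ndarray, min_size: int) -> tuple[int | None, float]:
    """Index k minimizing SSE of a two-segment linear fit of sorted y vs rank.

    Each segment y[:k], y[k:] gets its own least-squares line in rank order;
    the boundary of the best fit is the inflection where the slowly rising
    body of the sorted curve gives way to the rapidly increasing tail.
    Returns (k, gain) where gain is the SSE reduction relative to the
    single-line fit.  O(n) via prefix sums; ties break to the smallest k.
    """
    n = len(y)
    if n < 2 * min_size:
        return None, 0.0
    t = np.arange(n, dtype=float)
    c_t = np.concatenate([[0.0], np.cumsum(t)])
    c_t2 = np.concatenate([[0.0], np.cumsum(t * t)])
    c_y = np.concatenate([[0.0], np.cumsum(y)])
    c_y2 = np.concatenate([[0.0], np.cumsum(y * y)])
    c_ty = np.concatenate([[0.0], np.cumsum(t * y)])

    def seg_sse(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        m = (j - i).astype(float)
        st = c_t[j] - c_t[i]
        st2 = c_t2[j] - c_t2[i]
        sy = c_y[j] - c_y[i]
        sy2 = c_y2[j] - c_y2[i]
        sty = c_ty[j] - c_ty[i]
        vt = st2 - st * st / m
        vy = sy2 - sy * sy / m
        cty = sty - st * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = np.where(vt > 0, cty * cty / np.where(vt > 0, vt, 1.0), 0.0)
        return vy - fit

    ks = np.arange(min_size, n - min_size + 1)
    zeros = np.zeros_like(ks)
    ns = np.full_like(ks, n)
    sse = seg_sse(zeros, ks) + seg_sse(ks, ns)
    total_sse = float(seg_sse(np.array([0]), np.array([n]))[0])
    best = int(np.argmin(sse))
    return int(ks[best]), float(total_sse - sse[best])


def find_hypermutation_threshold(
    tmb_values,
    fallback: float = DEFAULT_HM_THRESHOLD,
    min_segment_fraction: float = MIN_SEGMENT_FRACTION,
    min_samples: int = MIN_SAMPLES_FOR_SEGMENTATION,
) -> ThresholdResult:
    """Cohort inflection point for the rapid increase in TMB.

    Sorts log1p(TMB) and places the boundary of the exact two-segment
    least-squares linear fit of the sorted curve against rank, subject
    to a minimum segment size of ``min_segment_fraction`` of the cohort.
    The threshold is the midpoint, on the raw TMB scale, between the two
    samples flanking the boundary.  Deterministic for fixed input; cohorts
    smaller than ``min_samples`` or with no variance return the fallback.
    """
    x = np.sort(np.asarray(tmb_values, dtype=float))
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("tmb values must be finite and non-negative")
    n = len(x)
    if n < min_samples:
        return ThresholdResult(fallback, None, degenerate=False, used_fallback=True)
    if np.allclose(x, x[0]):
        return ThresholdResult(fallback, None, degenerate=True, used_fallback=True)
    y = np.log1p(x)
    min_size = max(2, int(np.ceil(min_segment_fraction * n)))
    k, gain = _two_segment_split(y, min_size)
    if k is None or gain <= 0:
        return ThresholdResult(fallback, None, degenerate=True, used_fallback=True)
    threshold = float((x[k - 1] + x[k]) / 2.0)
    return ThresholdResult(threshold, k, degenerate=False, used_fallback=False)


def classify_hypermutated(tmb, threshold: float):
    """Strictly-greater comparison against the cohort threshold."""
    tmb = np.asarray(tmb, dtype=float)
    result = tmb > threshold
    if result.ndim == 0:
        return bool(result)
    return result


def cnv_event_counts(cnv_calls: pd.DataFrame, clinical: pd.DataFrame) -> pd.Series:
    """Per-sample count of high amplifications plus two-copy deletions.

    Used as the copy-number analogue of hypermutation status in the
    enrichment background model.
    """
    from .annotation import CNV_HIGH_AMP, CNV_TWO_COPY_DEL

    big = cnv_calls[cnv_calls["call"].isin([CNV_HIGH_AMP, CNV_TWO_COPY_DEL])]
    counts = big.groupby("sample_id").size()
    out = clinical["sample_id"].map(counts).fillna(0).astype(int)
    out.index = clinical["sample_id"]
    out.name = "cnv_event_count"
    return out


def find_count_cutoff(counts, fallback: float = 2.0) -> ThresholdResult:
    """Changepoint-chosen dichotomization cutoff for CNV event counts.

    Same two-segment scan as the TMB threshold, applied to per-sample
    high-amp/deep-del counts; samples strictly above the cutoff are the
    high-background category.
    """
    return find_hypermutation_threshold(counts, fallback=fallback)
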