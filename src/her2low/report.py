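"""Figure-style summary tables: alteration frequencies, an OncoPrint-style
sample × gene matrix export, and copy-count category summaries.

Everything is emitted as data tables (TSV-ready DataFrames); plotting is
left to downstream tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import HER2_LOW


def frequency_table(
    matrix: pd.DataFrame, clinical: pd.DataFrame, by=("her2_class",)
) -> pd.DataFrame:
    """Per-gene alteration frequency within each clinical subgroup."""
    meta = clinical.set_index("sample_id").reindex(matrix.index)
    rows = []
    for keys, idx in meta.groupby(list(by)).groups.items():
        if not isinstance(keys, tuple):
            keys = (keys,)
        sub = matrix.loc[idx]
        for gene in matrix.columns:
            rows.append(
                dict(
                    zip(by, keys),
                    gene=gene,
                    n=len(sub),
                    n_altered=int(sub[gene].sum()),
                    frequency=float(sub[gene].mean()) if len(sub) else np.nan,
                )
            )
    return pd.DataFrame(rows)


def oncoprint_matrix(
    mutation_matrix: pd.DataFrame,
    cnv_calls: pd.DataFrame,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Sample × gene event-string matrix consumable by oncoprint tools.

    Cells contain ``MUT``, ``AMP``, ``DEL``, combinations joined by ``;``,
    or empty.  Rows carry the HER2 class and ER status for track headers.
    """
    from .annotation import CNV_HIGH_AMP, CNV_TWO_COPY_DEL

    samples = list(mutation_matrix.index)
    genes = sorted(
        set(mutation_matrix.columns) | set(cnv_calls["gene"]),
        key=lambda g: -(mutation_matrix[g].sum() if g in mutation_matrix else 0),
    )
    grid = pd.DataFrame("", index=samples, columns=genes)
    for gene in mutation_matrix.columns:
        grid.loc[mutation_matrix[gene], gene] = "MUT"
    for _, row in cnv_calls.iterrows():
        if row["sample_id"] not in grid.index:
            continue
        tag = (
            "AMP"
            if row["call"] == CNV_HIGH_AMP
            else "DEL"
            if row["call"] == CNV_TWO_COPY_DEL
            else ""
        )
        if not tag:
            continue
        cur = grid.at[row["sample_id"], row["gene"]]
        grid.at[row["sample_id"], row["gene"]] = f"{cur};{tag}" if cur else tag
    meta = clinical.set_index("sample_id").reindex(samples)
    grid.insert(0, "er_status", meta["er_status"].to_numpy())
    grid.insert(0, "her2_class", meta["her2_class"].to_numpy())
    grid.index.name = "sample_id"
    return grid.reset_index()


def copy_count_summary(
    copy_counts: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Per-HER2-class copy-count medians and category proportions."""
    merged = copy_counts.merge(
        clinical[["sample_id", "her2_class"]], on="sample_id", how="left"
    )
    eligible = merged[merged["eligible"].astype(bool)]
    rows = []
    for her2, sub in eligible.groupby("her2_class"):
        counts = sub["category"].value_counts()
        row = {
            "her2_class": her2,
            "n_eligible": len(sub),
            "median_copies": float(sub["copies"].median()),
        }
        for cat in ("single_copy_deletion", "no_change", "allelic_gain"):
            row[f"n_{cat}"] = int(counts.get(cat, 0))
            row[f"frac_{cat}"] = float(counts.get(cat, 0) / len(sub)) if len(sub) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:  # HER2-low first for readability
        out = out.sort_values("her2_class", key=lambda s: s != HER2_LOW).reset_index(
            drop=True
        )
    return out
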