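"""ER-stratified association tests and Table-1-style baseline comparisons.

Two stratified procedures are provided:

* a generalized Cochran–Mantel–Haenszel (CMH) test for group × category
  tables pooled over strata — the *general association* flavor treats
  categories as nominal (chi-square, K−1 df); a *correlation* flavor with
  equally spaced scores is available for ordered categories (1 df);
* an asymptotic stratified Kruskal–Wallis (van Elteren-type) rank test:
  within-stratum midranks are centered per stratum and pooled into a
  quadratic-form statistic with a chi-square reference on (groups − 1) df,
  with ties handled by midranks.

Both use the exact conditional (hypergeometric / permutation) moments, so
with a single stratum the CMH statistic reduces to the classic
Mantel–Haenszel (N−1)-scaled chi-square, and the stratified rank test
reduces to the tie-corrected Kruskal–Wallis statistic.  No continuity
corrections are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    strata_used: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "strata_used": self.strata_used,
        }


def table_from_frame(
    df: pd.DataFrame, group: str, category: str, stratum: str
) -> np.ndarray:
    """Build a (groups × categories × strata) count array from tidy data."""
    ct = pd.crosstab([df[group]], [df[category], df[stratum]])
    groups = sorted(df[group].dropna().unique())
    cats = sorted(df[category].dropna().unique())
    strata = sorted(df[stratum].dropna().unique())
    out = np.zeros((len(groups), len(cats), len(strata)), dtype=int)
    for gi, g in enumerate(groups):
        for ci, c in enumerate(cats):
            for si, s in enumerate(strata):
                try:
                    out[gi, ci, si] = ct.loc[g, (c, s)]
                except KeyError:
                    pass
    return out


def _usable_strata(table: np.ndarray) -> list[int]:
    """Strata with at least two observations and no all-zero group/category margin issues."""
    keep = []
    for s in range(table.shape[2]):
        sub = table[:, :, s]
        n = sub.sum()
        if n < 2 or (sub.sum(axis=1) == 0).any():
            if n > 0:
                logger.warning("dropping stratum %d with a zero margin", s)
            continue
        keep.append(s)
    return keep


def cmh_general_association(table, kind: str = "general") -> TestResult:
    """Generalized CMH test for a 2 × K × S stratified contingency table.

    Parameters
    ----------
    table
        Integer counts of shape (2 groups, K categories, S strata).
    kind
        ``"general"`` (nominal categories, chi-square on K−1 df) or
        ``"correlation"`` (ordered categories with equally spaced scores,
        1 df).

    With S = 1 and K = 2 the general statistic equals the Mantel–Haenszel
    chi-square (N−1 scaling, no continuity correction).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim == 2:
        table = table[:, :, None]
    if table.ndim != 3 or table.shape[0] != 2:
        raise ValueError("table must have shape (2, K, S)")
    if table.sum() == 0:
        raise DegenerateInputError("all counts are zero")
    K = table.shape[1]
    keep = _usable_strata(table)
    if not keep:
        raise DegenerateInputError("no stratum has usable counts")

    if kind == "general":
        d = np.zeros(K - 1)
        V = np.zeros((K - 1, K - 1))
        for s in keep:
            sub = table[:, :, s]
            N = sub.sum()
            r1 = sub[0].sum()
            r2 = sub[1].sum()
            c = sub.sum(axis=0)
            d += sub[0, : K - 1] - r1 * c[: K - 1] / N
            cj = c[: K - 1]
            V += (
                r1
                * r2
                / (N**2 * (N - 1))
                * (np.diag(cj) * N - np.outer(cj, cj))
            )
        Vinv = np.linalg.pinv(V)
        statistic = float(d @ Vinv @ d)
        df = K - 1
        method = "cmh_general_association"
    elif kind == "correlation":
        b = np.arange(1, K + 1, dtype=float)  # equally spaced category scores
        num = 0.0
        var = 0.0
        for s in keep:
            sub = table[:, :, s]
            N = sub.sum()
            r1 = sub[0].sum()
            r2 = sub[1].sum()
            c = sub.sum(axis=0)
            num += b @ sub[0] - r1 * (b @ c) / N
            var += r1 * r2 / (N**2 * (N - 1)) * (N * (b**2 @ c) - (b @ c) ** 2)
        if var <= 0:
            statistic, df = 0.0, 1
        else:
            statistic = float(num**2 / var)
        df = 1
        method = "cmh_correlation"
    else:
        raise ValueError(f"unknown CMH kind: {kind!r}")

    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return TestResult(statistic, df, p, method, strata_used=len(keep))


def cmh_from_frame(
    df: pd.DataFrame,
    group: str,
    category: str,
    stratum: str,
    kind: str = "general",
) -> TestResult:
    """CMH test from a tidy sample-level table."""
    return cmh_general_association(
        table_from_frame(df, group, category, stratum), kind=kind
    )


def stratified_kruskal_wallis(values, groups, strata) -> TestResult:
    """Asymptotic stratified Kruskal–Wallis test.

    Within each stratum the observations receive midranks; the per-group
    rank sums, pooled over strata, form a linear statistic whose exact
    permutation mean and covariance (sampling without replacement within
    strata) give a quadratic form referred to chi-square on (G − 1) df.
    Strata with fewer than two observations are dropped with a warning.
    With a single stratum this equals the tie-corrected Kruskal–Wallis
    statistic (two groups: the squared tie-corrected normal-approximation
    Wilcoxon rank-sum z).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    if not (len(values) == len(groups) == len(strata)):
        raise ValueError("values, groups and strata must have equal length")
    glevels = np.unique(groups)
    G = len(glevels)
    if G < 2:
        raise DegenerateInputError("need at least two groups")
    gindex = {g: i for i, g in enumerate(glevels)}

    T = np.zeros(G)
    E = np.zeros(G)
    Cov = np.zeros((G, G))
    used = 0
    for s in np.unique(strata):
        mask = strata == s
        n_h = int(mask.sum())
        if n_h < 2:
            logger.warning("dropping stratum %r with a single sample", s)
            continue
        a = stats.rankdata(values[mask])  # midranks
        abar = a.mean()
        ss = float(((a - abar) ** 2).sum())
        g_h = groups[mask]
        n_hg = np.array([(g_h == g).sum() for g in glevels], dtype=float)
        for g in glevels:
            T[gindex[g]] += a[g_h == g].sum()
        E += n_hg * abar
        if ss > 0:
            factor = ss / (n_h * (n_h - 1))
            Cov += factor * (np.diag(n_hg) * n_h - np.outer(n_hg, n_hg))
        used += 1
    if used == 0:
        raise DegenerateInputError("no stratum has two or more samples")
    d = T - E
    statistic = float(d @ np.linalg.pinv(Cov) @ d)
    df = G - 1
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return TestResult(statistic, df, p, "stratified_kruskal_wallis", strata_used=used)


def baseline_tests(
    clinical: pd.DataFrame,
    group_col: str = "her2_class",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    durations: list[str] | None = None,
) -> pd.DataFrame:
    """Table-1-style baseline comparisons between the two HER2 groups.

    Categorical columns are compared with a chi-square test of
    independence, continuous columns with a Welch t-test, and duration
    columns with a two-sided Wilcoxon rank-sum test.  Columns with a
    single observed level are skipped with a note.
    """
    categorical = categorical or []
    continuous = continuous or []
    durations = durations or []
    glevels = clinical[group_col].dropna().unique()
    rows = []

    def add(variable, method, statistic, df, p, note=""):
        rows.append(
            {
                "variable": variable,
                "method": method,
                "statistic": statistic,
                "df": df,
                "p_value": p,
                "note": note,
            }
        )

    for col in categorical:
        sub = clinical[[group_col, col]].dropna()
        if sub[col].nunique() < 2 or sub[group_col].nunique() < 2:
            add(col, "chi_square", np.nan, np.nan, np.nan, "single level; skipped")
            continue
        ct = pd.crosstab(sub[group_col], sub[col])
        chi2, p, df, _ = stats.chi2_contingency(ct, correction=False)
        add(col, "chi_square", chi2, df, p)

    for col in continuous:
        sub = clinical[[group_col, col]].dropna()
        parts = [sub.loc[sub[group_col] == g, col] for g in glevels]
        if len(parts) < 2 or any(len(p_) < 2 for p_ in parts):
            add(col, "welch_t", np.nan, np.nan, np.nan, "insufficient data; skipped")
            continue
        t, p = stats.ttest_ind(parts[0], parts[1], equal_var=False)
        add(col, "welch_t", float(t), np.nan, float(p))

    for col in durations:
        sub = clinical[[group_col, col]].dropna()
        parts = [sub.loc[sub[group_col] == g, col] for g in glevels]
        if len(parts) < 2 or any(len(p_) < 1 for p_ in parts):
            add(col, "wilcoxon_rank_sum", np.nan, np.nan, np.nan, "insufficient data; skipped")
            continue
        stat, p = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
        add(col, "wilcoxon_rank_sum", float(stat), np.nan, float(p))

    return pd.DataFrame(rows)
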