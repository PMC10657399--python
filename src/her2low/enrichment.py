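"""Per-gene enrichment of genomic events between HER2-low and HER2-0.

For each gene and event class (any mutation, oncogenic mutation, oncogenic
CNV) a logistic regression models the per-sample event indicator on HER2
class, ER group (positive including ER-low vs negative) and a categorical
background-burden covariate (hypermutation status for mutations; a
changepoint-dichotomized high-amp/deep-del count for CNVs).  The HER2
coefficient is reported as an odds ratio with Wald 95% CI and two-tailed
Wald p; a likelihood-ratio test against the intercept-only model gates
genes at an LL q-value of 0.05; mutation genes are pre-filtered to those
altered in over 4% of either subcohort.  Coefficient and LL p-values are
Benjamini–Hochberg-corrected separately within each event-class family.
Models that do not converge within 500 iterations (including separated
fits) are excluded from the results and logged with a reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 500
COMMON_EVENT_THRESHOLD = 0.04
LL_GATE_Q = 0.05

#: absolute logit beyond which a fitted coefficient is treated as separation
_SEPARATION_BETA = 15.0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    Missing values are excluded from the correction and reinserted as
    missing; the remaining p-values must lie in [0, 1].  Output is
    order-preserving in p and elementwise >= p.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pv, method="fdr_bh")
    out[mask] = q
    return out


def build_alteration_matrix(
    events: pd.DataFrame,
    sample_ids,
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
) -> pd.DataFrame:
    """Samples × genes boolean matrix from an event table."""
    sample_ids = list(sample_ids)
    if events.empty:
        return pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    hit = events[[sample_col, gene_col]].drop_duplicates()
    mat = (
        pd.crosstab(hit[sample_col], hit[gene_col])
        .reindex(sample_ids, fill_value=0)
        .astype(bool)
    )
    mat.index.name = "sample_id"
    return mat


def select_common_events(
    matrix: pd.DataFrame, her2_low: pd.Series, threshold: float = COMMON_EVENT_THRESHOLD
) -> list[str]:
    """Genes altered in strictly more than ``threshold`` of either subcohort."""
    her2_low = her2_low.reindex(matrix.index).astype(bool)
    keep = []
    for gene in matrix.columns:
        f_low = matrix.loc[her2_low, gene].mean() if her2_low.any() else 0.0
        f_zero = matrix.loc[~her2_low, gene].mean() if (~her2_low).any() else 0.0
        if f_low > threshold or f_zero > threshold:
            keep.append(gene)
    return keep


@dataclass
class GeneFit:
    """Fitted enrichment model for one gene."""

    gene: str
    event_class: str = ""
    n_events: int = 0
    n_samples: int = 0
    converged: bool = False
    reason: str = ""
    n_iterations: int = 0
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_coef: float = np.nan
    ll_p: float = np.nan
    llf: float = np.nan
    ll_null: float = np.nan
    extra: dict = field(default_factory=dict)


def fit_gene_model(
    y,
    her2_low,
    er_positive,
    high_burden,
    max_iter: int = MAX_ITERATIONS,
    ll_null: str = "intercept",
) -> GeneFit:
    """Maximum-likelihood logistic fit of one gene's event indicator.

    Predictors are all categorical 0/1: HER2-low, ER-positive (ER-low
    merged in), and the background-burden category.  Returns Wald CI/p for
    the HER2 term and a likelihood-ratio p against the ``ll_null`` model
    (``"intercept"`` or ``"covariates"``, i.e. the model without the HER2
    term).  Separation and iteration exhaustion are reported as
    non-convergence; non-converged fits carry no estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack(
        [
            np.asarray(her2_low, dtype=float),
            np.asarray(er_positive, dtype=float),
            np.asarray(high_burden, dtype=float),
        ]
    )
    fit = GeneFit(gene="", n_events=int(y.sum()), n_samples=len(y))
    if y.min() == y.max():
        fit.reason = "degenerate outcome"
        return fit
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=max_iter, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit.reason = "separation"
        return fit
    fit.n_iterations = int(res.mle_retvals.get("iterations", max_iter))
    if not res.mle_retvals.get("converged", False):
        fit.reason = "not converged after max iterations"
        return fit
    if np.any(np.abs(res.params) > _SEPARATION_BETA) or not np.all(
        np.isfinite(res.bse)
    ):
        fit.reason = "separation"
        return fit
    beta = res.params[1]
    se = res.bse[1]
    fit.converged = True
    fit.odds_ratio = float(np.exp(beta))
    fit.ci_low = float(np.exp(beta - 1.959963984540054 * se))
    fit.ci_high = float(np.exp(beta + 1.959963984540054 * se))
    fit.p_coef = float(res.pvalues[1])
    fit.llf = float(res.llf)
    if ll_null == "intercept":
        null_llf = float(res.llnull)
        df = Xc.shape[1] - 1
    elif ll_null == "covariates":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_res = sm.Logit(y, np.delete(Xc, 1, axis=1)).fit(
                disp=False, maxiter=max_iter, method="newton"
            )
        null_llf = float(null_res.llf)
        df = 1
    else:
        raise ValueError(f"unknown ll_null: {ll_null!r}")
    fit.ll_null = null_llf
    lr = max(0.0, 2.0 * (fit.llf - null_llf))
    fit.ll_p = float(stats.chi2.sf(lr, df))
    return fit


RESULT_COLUMNS = [
    "gene",
    "event_class",
    "n_events",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_coef",
    "q_coef",
    "ll_p",
    "ll_q",
    "included",
    "converged",
    "n_iterations",
]


def run_enrichment(
    matrices: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    mutation_threshold: float = COMMON_EVENT_THRESHOLD,
    ll_gate_q: float = LL_GATE_Q,
    max_iter: int = MAX_ITERATIONS,
    ll_null: str = "intercept",
) -> tuple[pd.DataFrame, dict]:
    """Fit every gene in every event-class family and apply FDR control.

    Parameters
    ----------
    matrices
        Mapping event-class tag -> samples × genes boolean matrix.  Tags
        containing ``"cnv"`` are exempt from the common-event frequency
        filter and use the ``high_cnv_burden`` covariate; all other tags
        are filtered at ``mutation_threshold`` and use ``hypermutated``.
    covariates
        Indexed by sample_id with boolean columns ``her2_low``,
        ``er_positive`` (missing = sample excluded), ``hypermutated``,
        ``high_cnv_burden``.

    Returns the results table (converged fits only, sorted by q then p,
    BH families per event class) and a run manifest recording thresholds
    and every excluded gene with its reason.
    """
    manifest: dict = {
        "mutation_threshold": mutation_threshold,
        "ll_gate_q": ll_gate_q,
        "max_iterations": max_iter,
        "ll_null": ll_null,
        "families": {},
        "excluded": [],
    }
    modeled = covariates.dropna(subset=["er_positive"])
    n_er_missing = len(covariates) - len(modeled)
    manifest["samples_excluded_missing_er"] = int(n_er_missing)

    all_rows: list[pd.DataFrame] = []
    for event_class, matrix in matrices.items():
        mat = matrix.reindex(modeled.index).fillna(False)
        is_cnv = "cnv" in event_class.lower()
        if is_cnv:
            genes = [g for g in mat.columns if mat[g].any()]
            burden = modeled["high_cnv_burden"].astype(float)
        else:
            genes = select_common_events(
                mat, modeled["her2_low"], threshold=mutation_threshold
            )
            burden = modeled["hypermutated"].astype(float)
        manifest["families"][event_class] = {
            "genes_tested": len(genes),
            "frequency_filtered": not is_cnv,
        }
        fits = []
        for gene in genes:
            f = fit_gene_model(
                mat[gene].astype(float),
                modeled["her2_low"].astype(float),
                modeled["er_positive"].astype(float),
                burden,
                max_iter=max_iter,
                ll_null=ll_null,
            )
            f.gene = gene
            f.event_class = event_class
            if not f.converged:
                manifest["excluded"].append(
                    {"gene": gene, "event_class": event_class, "reason": f.reason}
                )
                logger.info("excluding %s (%s): %s", gene, event_class, f.reason)
            fits.append(f)
        rows = pd.DataFrame(
            [
                {
                    "gene": f.gene,
                    "event_class": f.event_class,
                    "n_events": f.n_events,
                    "odds_ratio": f.odds_ratio,
                    "ci_low": f.ci_low,
                    "ci_high": f.ci_high,
                    "p_coef": f.p_coef,
                    "ll_p": f.ll_p,
                    "converged": f.converged,
                    "n_iterations": f.n_iterations,
                }
                for f in fits
                if f.converged
            ]
        )
        if not rows.empty:
            rows["q_coef"] = bh_fdr(rows["p_coef"])
            rows["ll_q"] = bh_fdr(rows["ll_p"])
            rows["included"] = rows["ll_q"] < ll_gate_q
            all_rows.append(rows)

    if not all_rows:
        logger.warning("no genes produced a converged enrichment model")
        return pd.DataFrame(columns=RESULT_COLUMNS), manifest
    out = pd.concat(all_rows, ignore_index=True)
    out = out.sort_values(["q_coef", "p_coef"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS], manifest


def crude_odds_ratio(y, group) -> float:
    """Unadjusted 2×2 odds ratio of an event indicator vs a binary group."""
    y = np.asarray(y, dtype=bool)
    group = np.asarray(group, dtype=bool)
    a = np.sum(y & group)
    b = np.sum(~y & group)
    c = np.sum(y & ~group)
    d = np.sum(~y & ~group)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))
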