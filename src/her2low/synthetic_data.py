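"""Synthetic cohort generator for HER2-low vs HER2-0 comparison studies.

Generates clinical, mutation (MAF-dialect), copy-number (gene-level calls +
SEG-dialect segments) and gene-annotation tables with the joint structure
the downstream analysis assumes: a ~47/53 HER2-low/HER2-0 split, an ER
distribution that differs by HER2 class (the key confounder), per-gene
mutation frequencies that vary strongly with ER status (TP53, PIK3CA, CDH1,
GATA3, ESR1 tiers) plus high-amplification rates for CCND1/FGFR1/MYC, a
lognormal TMB body with a ~7% hypermutated uniform tail, Beta-distributed
tumor purity supported on [0.2, 1], and ERBB2 true copy numbers whose
distribution is shifted between HER2 groups and observed through the
purity-contamination forward model with Gaussian log2-ratio noise.

A truth table carries every latent quantity (true ER, true TMB and tail
membership, true ERBB2 copy number, per-gene alteration indicators) so
parameter-recovery tests are well-posed.  All randomness flows through a
single seeded generator; identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import ROLE_ONCOGENE, ROLE_TSG
from .burden import DEFAULT_PANEL_SIZES_MB
from .copy_number import ERBB2_REGION, forward_log2_ratio
from .errors import ConfigError, ConsistencyError

HER2_LOW = "her2_low"
HER2_ZERO = "her2_0"
ER_POSITIVE = "positive"
ER_LOW = "low"
ER_NEGATIVE = "negative"
ER_UNKNOWN = "unknown"

_ER_LEVELS = (ER_POSITIVE, ER_LOW, ER_NEGATIVE)


@dataclass(frozen=True)
class GeneProfile:
    """Planted mutation/CNV behaviour of one gene.

    ``mut_freq`` maps (her2_class, er_status) -> per-sample mutation
    probability; ``her2_log_odds`` is an additional logit shift applied to
    HER2-low samples on top of the cell frequency (0 by default, so the
    cell frequencies are used as-is).  ``cnv_freq`` is the rate of the
    gene's oncogenic CNV event (high amplification for oncogenes, two-copy
    deletion for TSGs).
    """

    gene: str
    role: str
    mut_freq: dict
    cnv_freq: float = 0.0
    her2_log_odds: float = 0.0

    def mutation_prob(self, her2_class: str, er_status: str) -> float:
        p = self.mut_freq[(her2_class, er_status)]
        if self.her2_log_odds != 0.0 and her2_class == HER2_LOW:
            logit = np.log(p / (1 - p)) + self.her2_log_odds
            p = 1.0 / (1.0 + np.exp(-logit))
        return float(p)


def _cells(low: tuple, zero: tuple) -> dict:
    """Expand (pos, low, neg) frequency triples per HER2 class into cell keys."""
    out = {}
    for her2, triple in ((HER2_LOW, low), (HER2_ZERO, zero)):
        for er, p in zip(_ER_LEVELS, triple):
            out[(her2, er)] = p
    return out


def default_gene_profiles() -> list[GeneProfile]:
    """Study-calibrated per-gene frequencies by ER status within HER2 class.

    Triples are (ER-positive, ER-low, ER-negative) oncogenic-alteration
    frequencies; the first tuple is HER2-low, the second HER2-0.
    """
    return [
        GeneProfile("TP53", ROLE_TSG, _cells((0.226, 0.455, 0.798), (0.265, 0.818, 0.872))),
        GeneProfile("PIK3CA", ROLE_ONCOGENE, _cells((0.382, 0.227, 0.149), (0.438, 0.364, 0.118))),
        GeneProfile("CDH1", ROLE_TSG, _cells((0.175, 0.227, 0.053), (0.164, 0.182, 0.031))),
        GeneProfile("GATA3", ROLE_TSG, _cells((0.161, 0.136, 0.021), (0.125, 0.0, 0.010))),
        GeneProfile("ESR1", ROLE_ONCOGENE, _cells((0.134, 0.091, 0.0), (0.116, 0.0, 0.0)), cnv_freq=0.01),
        GeneProfile("MTOR", ROLE_ONCOGENE, _cells((0.055, 0.055, 0.055), (0.030, 0.030, 0.030))),
        GeneProfile("MAP3K1", ROLE_TSG, _cells((0.055, 0.055, 0.040), (0.085, 0.085, 0.050))),
        GeneProfile("NF1", ROLE_TSG, _cells((0.030, 0.030, 0.030), (0.055, 0.055, 0.055))),
        GeneProfile("CCND1", ROLE_ONCOGENE, _cells((0.02,) * 3, (0.02,) * 3), cnv_freq=0.132),
        GeneProfile("FGFR1", ROLE_ONCOGENE, _cells((0.02,) * 3, (0.02,) * 3), cnv_freq=0.110),
        GeneProfile("MYC", ROLE_ONCOGENE, _cells((0.01,) * 3, (0.01,) * 3), cnv_freq=0.061),
        GeneProfile("PTEN", ROLE_TSG, _cells((0.05,) * 3, (0.06,) * 3), cnv_freq=0.04),
    ]


@dataclass(frozen=True)
class Erbb2Model:
    """True ERBB2 copy number per HER2 class and the observation noise.

    True copies are truncated-normal (>= ``cn_floor``); the observed
    segment log2 ratio is the purity-contamination forward model plus
    Gaussian noise of SD ``noise_sd``.
    """

    cn_mean_low: float = 2.05
    cn_mean_zero: float = 1.79
    cn_sd: float = 0.55
    cn_floor: float = 0.5
    noise_sd: float = 0.10


@dataclass(frozen=True)
class PurityModel:
    """Tumor purity = floor + (1 - floor) * Beta(alpha, beta); support [floor, 1]."""

    alpha: float = 2.0
    beta: float = 2.0
    floor: float = 0.2


@dataclass(frozen=True)
class TmbModel:
    """Lognormal TMB body with a uniform hypermutated tail (mut/Mb).

    The model describes the latent pre-filter mutation burden; the default
    body median (8.34) is chosen so that after the germline filter removes
    flagged, non-rescued variants (fraction c*(1-r) ~ 11% at the default
    contamination/rescue rates) the observed TMB median lands near the
    7.3-7.6 mut/Mb typical of metastatic breast cancer panels.
    """

    log_mean: float = float(np.log(8.34))
    log_sd: float = 0.35
    tail_fraction: float = 0.07
    tail_low: float = 20.0
    tail_high: float = 60.0


@dataclass
class SimulationConfig:
    """All generator knobs; defaults reproduce the study-scale cohort."""

    n_samples: int = 1039
    seed: int = 0
    her2_low_prevalence: float = 0.469
    # (ER-positive, ER-low, ER-negative) conditional on HER2 class
    er_positive_given_her2: dict = field(
        default_factory=lambda: {
            HER2_LOW: (0.7676, 0.0373, 0.1951),
            HER2_ZERO: (0.6098, 0.0381, 0.3521),
        }
    )
    er_missing_rate: float = 0.006
    ihc_2plus_given_low: float = 0.25
    ihc_nos_rate: float = 0.02
    specimen_probs: dict = field(
        default_factory=lambda: {
            "primary": 0.229,
            "local_recurrence": 0.023,
            "metastasis": 0.748,
        }
    )
    panel_version_probs: dict = field(
        default_factory=lambda: {"v1": 0.060, "v2": 0.258, "v3": 0.682}
    )
    panel_sizes_mb: dict = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES_MB))
    gene_profiles: list = field(default_factory=default_gene_profiles)
    erbb2_log2r_model: Erbb2Model = field(default_factory=Erbb2Model)
    purity_model: PurityModel = field(default_factory=PurityModel)
    tmb_model: TmbModel = field(default_factory=TmbModel)
    germline_contamination_rate: float = 0.15
    cosmic_rescue_rate: float = 0.25
    purity_missing_rate: float = 0.10
    segment_missing_rate: float = 0.05
    n_filler_genes: int = 30
    n_off_panel_genes: int = 3

    def validate(self) -> "SimulationConfig":
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        probs = {
            "her2_low_prevalence": self.her2_low_prevalence,
            "germline_contamination_rate": self.germline_contamination_rate,
            "cosmic_rescue_rate": self.cosmic_rescue_rate,
            "purity_missing_rate": self.purity_missing_rate,
            "segment_missing_rate": self.segment_missing_rate,
            "er_missing_rate": self.er_missing_rate,
            "ihc_2plus_given_low": self.ihc_2plus_given_low,
            "ihc_nos_rate": self.ihc_nos_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for her2, triple in self.er_positive_given_her2.items():
            if len(triple) != 3 or any(not 0 <= t <= 1 for t in triple):
                raise ConfigError(
                    f"er_positive_given_her2[{her2!r}] must be three probabilities"
                )
            if abs(sum(triple) - 1.0) > 1e-6:
                raise ConfigError(
                    f"er_positive_given_her2[{her2!r}] must sum to 1"
                )
        for dname, d in (
            ("specimen_probs", self.specimen_probs),
            ("panel_version_probs", self.panel_version_probs),
        ):
            if abs(sum(d.values()) - 1.0) > 1e-3:
                raise ConfigError(f"{dname} must sum to 1")
        if not 0 < self.purity_model.floor < 1:
            raise ConfigError("purity_model.floor must lie in (0, 1)")
        for gp in self.gene_profiles:
            for cell, p in gp.mut_freq.items():
                if not 0 <= p <= 1:
                    raise ConfigError(
                        f"gene_profiles[{gp.gene}].mut_freq{cell} must be in [0, 1]"
                    )
            if not 0 <= gp.cnv_freq <= 1:
                raise ConfigError(f"gene_profiles[{gp.gene}].cnv_freq must be in [0, 1]")
        return self


@dataclass
class Cohort:
    """Generated tables keyed by sample_id, plus the latent truth table."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    cnv_calls: pd.DataFrame
    segments: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _truncated_normal(rng, mean, sd, floor, size):
    """Draw N(mean, sd) truncated below at floor, by rejection (vectorized)."""
    out = rng.normal(mean, sd, size=size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(
            np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
            sd,
            size=int(bad.sum()),
        )
        bad = out < floor
    return out


_MAF_TSG_CLASSES = ["Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site", "Missense_Mutation"]
_MAF_TSG_WEIGHTS = [0.30, 0.30, 0.10, 0.30]
_MAF_ONC_CLASSES = ["Missense_Mutation", "In_Frame_Del"]
_MAF_ONC_WEIGHTS = [0.90, 0.10]
_ONC_LABELS = ["oncogenic", "likely_oncogenic", "predicted_oncogenic"]


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort; reproducible given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = np.array([f"S{i:05d}" for i in range(n)])

    # --- clinical backbone ------------------------------------------------
    her2_low = rng.random(n) < config.her2_low_prevalence
    her2_class = np.where(her2_low, HER2_LOW, HER2_ZERO)

    er_true = np.empty(n, dtype=object)
    for cls in (HER2_LOW, HER2_ZERO):
        mask = her2_class == cls
        triple = np.asarray(config.er_positive_given_her2[cls], dtype=float)
        er_true[mask] = rng.choice(_ER_LEVELS, size=int(mask.sum()), p=triple / triple.sum())

    er_percent = np.zeros(n, dtype=float)
    er_percent[er_true == ER_POSITIVE] = rng.integers(
        10, 101, size=int((er_true == ER_POSITIVE).sum())
    )
    er_percent[er_true == ER_LOW] = rng.integers(
        1, 10, size=int((er_true == ER_LOW).sum())
    )
    er_status = er_true.copy()
    er_miss = rng.random(n) < config.er_missing_rate
    er_status[er_miss] = ER_UNKNOWN
    er_percent_rec = er_percent.copy()
    er_percent_rec[er_miss] = np.nan

    ihc = np.where(
        her2_low, np.where(rng.random(n) < config.ihc_2plus_given_low, "2+", "1+"), "0"
    ).astype(object)
    ihc[rng.random(n) < config.ihc_nos_rate] = "NOS"

    pm = config.purity_model
    purity_true = pm.floor + (1.0 - pm.floor) * rng.beta(pm.alpha, pm.beta, size=n)
    purity = purity_true.copy()
    purity[rng.random(n) < config.purity_missing_rate] = np.nan

    specimen = rng.choice(
        list(config.specimen_probs), size=n, p=list(config.specimen_probs.values())
    )
    panel = rng.choice(
        list(config.panel_version_probs),
        size=n,
        p=list(config.panel_version_probs.values()),
    )
    panel_mb = np.vectorize(config.panel_sizes_mb.__getitem__)(panel)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "her2_class": her2_class,
            "ihc_score": ihc,
            "er_status": er_status,
            "er_percent": er_percent_rec,
            "purity": purity,
            "specimen_type": specimen,
            "panel_version": panel,
        }
    )

    # --- TMB and passenger load ------------------------------------------
    tm = config.tmb_model
    hyper_true = rng.random(n) < tm.tail_fraction
    tmb_true = np.where(
        hyper_true,
        rng.uniform(tm.tail_low, tm.tail_high, size=n),
        rng.lognormal(tm.log_mean, tm.log_sd, size=n),
    )
    n_total = np.round(tmb_true * panel_mb).astype(int)

    # --- driver mutations per gene profile --------------------------------
    profiles = list(config.gene_profiles)
    driver_rows = []
    mut_truth = {}
    for gp in profiles:
        p_vec = np.array(
            [gp.mutation_prob(h, e) for h, e in zip(her2_class, er_true)]
        )
        hit = rng.random(n) < p_vec
        mut_truth[gp.gene] = hit
        idx = np.flatnonzero(hit)
        if gp.role == ROLE_TSG:
            classes = rng.choice(_MAF_TSG_CLASSES, size=len(idx), p=_MAF_TSG_WEIGHTS)
            # truncating TSG drivers are sometimes unlabeled, exercising the
            # LOF-in-TSG branch; missense drivers carry a label
            labels = np.where(
                rng.random(len(idx)) < 0.5,
                rng.choice(_ONC_LABELS, size=len(idx)),
                "none",
            ).astype(object)
            truncating = np.isin(classes, _MAF_TSG_CLASSES[:3])
            labels[~truncating] = rng.choice(
                _ONC_LABELS, size=int((~truncating).sum())
            )
        else:
            classes = rng.choice(_MAF_ONC_CLASSES, size=len(idx), p=_MAF_ONC_WEIGHTS)
            labels = rng.choice(_ONC_LABELS, size=len(idx)).astype(object)
        for j, i in enumerate(idx):
            driver_rows.append((sample_ids[i], gp.gene, classes[j], labels[j]))

    # --- passenger mutations ----------------------------------------------
    filler_genes = [f"GENE{i:03d}" for i in range(1, config.n_filler_genes + 1)]
    off_panel = filler_genes[-config.n_off_panel_genes:] if config.n_off_panel_genes else []
    passenger_pool = np.array([gp.gene for gp in profiles] + filler_genes)
    n_drivers = np.zeros(n, dtype=int)
    for gp in profiles:
        n_drivers += mut_truth[gp.gene]
    n_pass = np.maximum(n_total - n_drivers, 0)
    pass_sample = np.repeat(np.arange(n), n_pass)
    m = len(pass_sample)
    pass_gene = rng.choice(passenger_pool, size=m)
    pass_class = np.where(rng.random(m) < 0.25, "Silent", "Missense_Mutation")
    pass_label = np.where(rng.random(m) < 0.1, "vus", "none")

    sample_col = np.concatenate(
        [np.array([r[0] for r in driver_rows], dtype=object), sample_ids[pass_sample]]
    )
    gene_col = np.concatenate(
        [np.array([r[1] for r in driver_rows], dtype=object), pass_gene]
    )
    class_col = np.concatenate(
        [np.array([r[2] for r in driver_rows], dtype=object), pass_class]
    )
    label_col = np.concatenate(
        [np.array([r[3] for r in driver_rows], dtype=object), pass_label]
    )
    nv = len(sample_col)

    flagged = rng.random(nv) < config.germline_contamination_rate
    gnomad = flagged & (rng.random(nv) < 0.8)
    clinvar = flagged & (rng.random(nv) < 0.4)
    neither = flagged & ~gnomad & ~clinvar
    gnomad = gnomad | neither  # a flagged variant carries at least one flag
    rescued = flagged & (rng.random(nv) < config.cosmic_rescue_rate)
    cosmic = np.where(
        rescued, rng.integers(2, 50, size=nv), (rng.random(nv) < 0.2).astype(int)
    )

    variants = pd.DataFrame(
        {
            "Hugo_Symbol": gene_col,
            "Tumor_Sample_Barcode": sample_col,
            "Variant_Classification": class_col,
            "oncokb_label": label_col,
            "gnomad_present": gnomad,
            "clinvar_present": clinvar,
            "cosmic_count": cosmic,
        }
    ).sort_values(["Tumor_Sample_Barcode", "Hugo_Symbol"], kind="mergesort").reset_index(
        drop=True
    )

    # --- gene-level CNV calls ----------------------------------------------
    cnv_rows = []
    cnv_truth = {}
    for gp in profiles:
        hit = rng.random(n) < gp.cnv_freq
        cnv_truth[gp.gene] = hit
        call = "high_amplification" if gp.role == ROLE_ONCOGENE else "two_copy_deletion"
        for i in np.flatnonzero(hit):
            copies = int(rng.integers(7, 30)) if call == "high_amplification" else 0
            cnv_rows.append((sample_ids[i], gp.gene, call, copies))
        # non-oncogenic CNV noise populating the VUS category
        vus_call = "amplification" if gp.role == ROLE_ONCOGENE else "single_copy_deletion"
        vus_hit = (rng.random(n) < 0.03) & ~hit
        for i in np.flatnonzero(vus_hit):
            copies = int(rng.integers(3, 7)) if vus_call == "amplification" else 1
            cnv_rows.append((sample_ids[i], gp.gene, vus_call, copies))
    cnv_calls = pd.DataFrame(
        cnv_rows, columns=["sample_id", "gene", "call", "copies_called"]
    ).sort_values(["sample_id", "gene"], kind="mergesort").reset_index(drop=True)

    # --- ERBB2 segments ----------------------------------------------------
    em = config.erbb2_log2r_model
    cn_mean = np.where(her2_low, em.cn_mean_low, em.cn_mean_zero)
    erbb2_cn = _truncated_normal(rng, cn_mean, em.cn_sd, em.cn_floor, n)
    log2r = forward_log2_ratio(erbb2_cn, purity_true) + rng.normal(
        0.0, em.noise_sd, size=n
    )
    chrom, gstart, gend = ERBB2_REGION
    has_seg = rng.random(n) >= config.segment_missing_rate
    seg = pd.DataFrame(
        {
            "sample_id": sample_ids[has_seg],
            "chrom": chrom,
            "start": gstart - 50_000,
            "end": gend + 50_000,
            "log2_ratio": np.round(log2r[has_seg], 6),
        }
    )
    # filler segments on other chromosomes for format realism
    filler_seg = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "chrom": "1",
            "start": 1_000_000,
            "end": 2_000_000,
            "log2_ratio": np.round(rng.normal(0.0, 0.1, size=n), 6),
        }
    )
    segments = (
        pd.concat([seg, filler_seg], ignore_index=True)
        .sort_values(["sample_id", "chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- gene annotations ----------------------------------------------------
    ann_rows = [
        {"gene": gp.gene, "role": gp.role, "panel_versions": "v1,v2,v3"}
        for gp in profiles
    ]
    for g in filler_genes:
        versions = "v3" if g in off_panel else "v1,v2,v3"
        ann_rows.append({"gene": g, "role": "other", "panel_versions": versions})
    annotations = pd.DataFrame(ann_rows)

    # --- truth table ----------------------------------------------------------
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "her2_class": her2_class,
            "er_status_true": er_true,
            "purity_true": purity_true,
            "tmb_true": tmb_true,
            "hypermutated_true": hyper_true,
            "erbb2_cn_true": erbb2_cn,
        }
    )
    for gp in profiles:
        truth[f"mut_{gp.gene}"] = mut_truth[gp.gene]
        truth[f"cnv_{gp.gene}"] = cnv_truth[gp.gene]

    return Cohort(clinical, variants, cnv_calls, segments, annotations, truth, config)


def emit_truth(cohort: Cohort) -> pd.DataFrame:
    """Latent truth table, one row per sample, after a consistency audit."""
    clin_ids = list(cohort.clinical["sample_id"])
    truth_ids = list(cohort.truth["sample_id"])
    if sorted(clin_ids) != sorted(truth_ids) or len(set(truth_ids)) != len(truth_ids):
        raise ConsistencyError("truth table sample IDs do not match the cohort")
    return cohort.truth


def simulate_alteration_matrix(
    n_samples: int,
    n_genes: int,
    seed: int,
    base_freq: float = 0.10,
    her2_log_odds: float = 0.0,
    planted_gene: int | None = None,
    planted_log_odds: float = 0.0,
    er_effect_log_odds: float = 0.7,
    her2_low_prevalence: float = 0.469,
    er_positive_given_low: float = 0.80,
    er_positive_given_zero: float = 0.65,
    hypermutated_fraction: float = 0.07,
    hm_log_odds: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct samples × genes Bernoulli simulator for enrichment studies.

    Event probabilities follow a logistic model with an ER-positive effect,
    a hypermutation effect, and a HER2-low effect of ``her2_log_odds`` for
    every gene (``planted_log_odds`` instead for ``planted_gene``).  ER
    prevalence differs by HER2 class, so HER2 and ER are confounded as in
    the study cohort.  Returns (matrix, covariates) ready for
    :func:`her2low.enrichment.run_enrichment`.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    her2 = rng.random(n_samples) < her2_low_prevalence
    p_er = np.where(her2, er_positive_given_low, er_positive_given_zero)
    er_pos = rng.random(n_samples) < p_er
    hm = rng.random(n_samples) < hypermutated_fraction

    base_logit = np.log(base_freq / (1 - base_freq))
    per_sample = (
        base_logit
        + er_effect_log_odds * (er_pos - 0.5)
        + hm_log_odds * hm
    )
    logits = per_sample[:, None] + her2_log_odds * her2[:, None] * np.ones(
        (1, n_genes)
    )
    if planted_gene is not None:
        logits[:, planted_gene] = per_sample + planted_log_odds * her2
    probs = 1.0 / (1.0 + np.exp(-logits))
    events = rng.random((n_samples, n_genes)) < probs
    matrix = pd.DataFrame(
        events,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"G{j:03d}" for j in range(n_genes)],
    )
    covariates = pd.DataFrame(
        {
            "her2_low": her2,
            "er_positive": er_pos.astype(float),
            "hypermutated": hm,
            "high_cnv_burden": hm,
        },
        index=matrix.index,
    )
    return matrix, covariates


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable view of a config (gene profiles flattened)."""
    d = asdict(config)
    d["gene_profiles"] = [
        {
            "gene": gp.gene,
            "role": gp.role,
            "cnv_freq": gp.cnv_freq,
            "her2_log_odds": gp.her2_log_odds,
            "mut_freq": {f"{h}|{e}": p for (h, e), p in gp.mut_freq.items()},
        }
        for gp in config.gene_profiles
    ]
    return d
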