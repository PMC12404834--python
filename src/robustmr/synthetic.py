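"""Synthetic GWAS/eQTL summary statistics with known ground truth.

Generates two-sample (and three-sample) per-SNP association tables with
the statistical structure two-sample MR assumes: instrument strengths
gamma_j with measurement error governed by 1/sqrt(2 n maf(1-maf)),
horizontal pleiotropy that is balanced, directional, or correlated
(confounder-driven, violating InSIDE and planting a second
profile-likelihood mode), p-value-based instrument selection in the
same sample (winner's curse) or an independent third sample, an
exposure -> mediator -> outcome chain, and a small cis region with an
LD block structure for the drug-target arm.

Every generator is a pure function of (config, seed). Defaults emulate
the data sources of a drug-target MR study of a blood cis-eQTL exposure
(n ~ 30,000) against biobank binary-outcome GWAS (effective n ~ 15,000
on the log-odds scale): lead-eQTL-strength instruments (gamma sd 0.4),
balanced pleiotropy sd 0.01, and a 40% confounded fraction for
two-pathway fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .sumstats import HarmonizedDataset, LDMatrix, SummaryStats

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


@dataclass(frozen=True)
class GammaSpec:
    """Distribution of true instrument strengths."""

    kind: str = "normal"  # "normal" | "spike_slab"
    sd: float = 0.4
    slab_fraction: float = 0.2  # spike_slab only
    spike_sd: float | None = None  # spike_slab only; defaults to sd / 10

    def draw(self, p: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(0.0, self.sd, p)
        if self.kind == "spike_slab":
            slab = rng.random(p) < self.slab_fraction
            out = rng.normal(0.0, self.spike_sd if self.spike_sd is not None else self.sd / 10.0, p)
            out[slab] = rng.normal(0.0, self.sd, slab.sum())
            return out
        raise ValidationError(f"unknown gamma_dist kind {self.kind!r}")


@dataclass(frozen=True)
class PleiotropySpec:
    """Horizontal-pleiotropy structure of the direct SNP-outcome effects.

    mode 'none': alpha_j = 0. 'balanced': alpha_j ~ N(0, tau^2).
    'directional': alpha_j ~ N(mu, tau^2). 'correlated': a fraction
    ``fraction`` of SNPs act through a confounder so that alpha_j =
    confounder_shift * gamma_j + N(0, tau^2) — their apparent effect is
    beta + confounder_shift, a second profile mode.
    """

    mode: str = "none"  # none | balanced | directional | correlated
    tau: float = 0.01
    mu: float = 0.0
    fraction: float = 0.4
    confounder_shift: float = -0.6

    def draw(self, gamma: np.ndarray, rng: np.random.Generator):
        p = len(gamma)
        labels = np.array(["valid"] * p, dtype=object)
        if self.mode == "none":
            return np.zeros(p), labels
        if self.mode == "balanced":
            return rng.normal(0.0, self.tau, p), labels
        if self.mode == "directional":
            return rng.normal(self.mu, self.tau, p), labels
        if self.mode == "correlated":
            if not 0 <= self.fraction <= 1:
                raise ValidationError("confounded fraction must lie in [0, 1]")
            conf = rng.random(p) < self.fraction
            alpha = rng.normal(0.0, self.tau, p)
            alpha[conf] += self.confounder_shift * gamma[conf]
            labels[conf] = "confounder"
            return alpha, labels
        raise ValidationError(f"unknown pleiotropy mode {self.mode!r}")


@dataclass(frozen=True)
class MediationSpec:
    """Exposure -> mediator -> outcome chain parameters."""

    theta_xm: float = 0.5  # exposure effect on the mediator
    theta_my: float = 0.2  # mediator effect on the outcome
    theta_direct: float = 0.2  # direct exposure effect on the outcome
    mediator_pleiotropy_sd: float = 0.1  # SNP effects on the mediator not via the exposure
    n_m: int = 30_000  # effective sample size of the mediator GWAS

    @property
    def total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def indirect(self) -> float:
        return self.theta_xm * self.theta_my


@dataclass(frozen=True)
class SelectionSpec:
    """Instrument selection: none, same-sample (winner's curse), or three-sample."""

    mode: str = "none"  # none | same_sample | three_sample
    p_threshold: float = 1e-4


@dataclass(frozen=True)
class SimConfig:
    p: int = 100
    beta: float = 0.3
    gamma_dist: GammaSpec = field(default_factory=GammaSpec)
    n_x: int = 30_000
    n_y: int = 15_000
    maf_range: tuple = (0.1, 0.5)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    mediation: MediationSpec | None = None
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    binary_outcome: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.p < 1:
            raise ValidationError("p must be >= 1")
        if self.n_x < 1 or self.n_y < 1:
            raise ValidationError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class SimTruth:
    """Generating parameters behind a synthetic dataset."""

    config: SimConfig
    gamma: np.ndarray
    alpha: np.ndarray
    pathway_label: np.ndarray
    beta: float
    maf: np.ndarray
    snp_ids: np.ndarray
    selection_log: dict = field(default_factory=dict)
    total: float | None = None
    direct: float | None = None
    indirect: float | None = None
    extra: dict = field(default_factory=dict)


def _se_from_n(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _table(snp, ea, oa, eaf, beta, se, n, label) -> SummaryStats:
    return SummaryStats(
        pd.DataFrame(
            {
                "SNP": snp, "EA": ea, "OA": oa, "EAF": eaf,
                "BETA": beta, "SE": se, "P": _two_sided_p(beta, se), "N": n,
            }
        ),
        trait_label=label,
    )


def _alleles(p: int, rng: np.random.Generator):
    idx = rng.integers(len(_ALLELE_PAIRS), size=p)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in idx], dtype=object)
    return ea, oa


def simulate_two_sample(cfg: SimConfig):
    """Draw (exposure table, outcome table, truth) under ``cfg``.

    Observed gamma_hat ~ N(gamma, sigma_x^2) and
    Gamma_hat ~ N(beta*gamma + alpha, sigma_y^2), independent across
    the two samples. Selection (if any) subsets both tables: same-sample
    selection conditions on the exposure estimates used downstream
    (winner's curse present); three-sample selection conditions on an
    independent replicate (curse absent).
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    snp = np.array([f"rs{i + 1}" for i in range(p)], dtype=object)
    ea, oa = _alleles(p, rng)
    maf = rng.uniform(*cfg.maf_range, p)
    gamma = cfg.gamma_dist.draw(p, rng)
    alpha, labels = cfg.pleiotropy.draw(gamma, rng)
    sx = _se_from_n(maf, cfg.n_x)
    sy = _se_from_n(maf, cfg.n_y)
    gamma_hat = gamma + sx * rng.standard_normal(p)
    Gamma_hat = cfg.beta * gamma + alpha + sy * rng.standard_normal(p)

    sel_log = {"mode": cfg.selection.mode}
    keep = np.ones(p, dtype=bool)
    if cfg.selection.mode == "same_sample":
        keep = _two_sided_p(gamma_hat, sx) < cfg.selection.p_threshold
        sel_log["p_threshold"] = cfg.selection.p_threshold
    elif cfg.selection.mode == "three_sample":
        gamma_rep = gamma + sx * rng.standard_normal(p)
        keep = _two_sided_p(gamma_rep, sx) < cfg.selection.p_threshold
        sel_log["p_threshold"] = cfg.selection.p_threshold
    elif cfg.selection.mode != "none":
        raise ValidationError(f"unknown selection mode {cfg.selection.mode!r}")
    sel_log["n_selected"] = int(keep.sum())
    sel_log["selected_ids"] = [str(s) for s in snp[keep]]

    exposure = _table(snp[keep], ea[keep], oa[keep], maf[keep],
                      gamma_hat[keep], sx[keep], cfg.n_x, "exposure")
    outcome = _table(snp[keep], ea[keep], oa[keep], maf[keep],
                     Gamma_hat[keep], sy[keep], cfg.n_y, "outcome")
    truth = SimTruth(
        config=cfg, gamma=gamma[keep], alpha=alpha[keep],
        pathway_label=labels[keep], beta=cfg.beta, maf=maf[keep],
        snp_ids=snp[keep], selection_log=sel_log,
    )
    return exposure, outcome, truth


def as_harmonized(exposures, outcome: SummaryStats) -> HarmonizedDataset:
    """Fast join of already-aligned simulator tables (no allele work).

    Simulator outputs share SNP order and orientation by construction;
    this skips the per-SNP harmonization loop for repeated-fit studies.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    ref = exposures[0].table
    for t in exposures[1:] + [outcome]:
        if not np.array_equal(t.table["SNP"].to_numpy(), ref["SNP"].to_numpy()):
            raise ValidationError("as_harmonized requires identically ordered tables")
    return HarmonizedDataset(
        snp_ids=ref["SNP"].to_numpy(dtype=object),
        exposure_beta=np.column_stack([t.table["BETA"].to_numpy() for t in exposures]),
        exposure_se=np.column_stack([t.table["SE"].to_numpy() for t in exposures]),
        outcome_beta=outcome.table["BETA"].to_numpy(),
        outcome_se=outcome.table["SE"].to_numpy(),
        exposure_pvalue=np.column_stack([t.table["P"].to_numpy() for t in exposures]),
        effect_allele=ref["EA"].to_numpy(dtype=object),
        other_allele=ref["OA"].to_numpy(dtype=object),
        exposure_eaf=ref["EAF"].to_numpy(),
        outcome_eaf=outcome.table["EAF"].to_numpy(),
        meta={
            "exposure_labels": [t.trait_label or f"exposure{k+1}" for k, t in enumerate(exposures)],
            "outcome_label": outcome.trait_label or "outcome",
        },
    )


def simulate_mediation(cfg: SimConfig):
    """Exposure/mediator/outcome chain; returns (ds_xy, ds_xm, ds_my, ds_xmy, truth).

    SNP effect on the mediator is theta_xm*gamma_j + eta_j (eta = the
    mediator's own pleiotropy); on the outcome it is
    (theta_direct + theta_xm*theta_my)*gamma_j + theta_my*eta_j +
    alpha_j. Each returned dataset is an independent two-sample
    realization (fresh measurement noise), so cross-dataset error
    correlations are zero by construction.
    """
    if cfg.mediation is None:
        raise ValidationError("cfg.mediation must be set")
    med = cfg.mediation
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    snp = np.array([f"rs{i + 1}" for i in range(p)], dtype=object)
    ea, oa = _alleles(p, rng)
    maf = rng.uniform(*cfg.maf_range, p)
    gamma = cfg.gamma_dist.draw(p, rng)
    alpha, labels = cfg.pleiotropy.draw(gamma, rng)
    eta = rng.normal(0.0, med.mediator_pleiotropy_sd, p)
    gamma_m = med.theta_xm * gamma + eta
    Gamma = med.total * gamma + med.theta_my * eta + alpha
    sx = _se_from_n(maf, cfg.n_x)
    sm = _se_from_n(maf, med.n_m)
    sy = _se_from_n(maf, cfg.n_y)

    def _exp(noise_scale, mean, label, n):
        return _table(snp, ea, oa, maf, mean + noise_scale * rng.standard_normal(p),
                      noise_scale, n, label)

    ds_xy = as_harmonized(_exp(sx, gamma, "exposure", cfg.n_x),
                          _exp(sy, Gamma, "outcome", cfg.n_y))
    ds_xm = as_harmonized(_exp(sx, gamma, "exposure", cfg.n_x),
                          _exp(sm, gamma_m, "mediator", med.n_m))
    ds_my = as_harmonized(_exp(sm, gamma_m, "mediator", med.n_m),
                          _exp(sy, Gamma, "outcome", cfg.n_y))
    ds_xmy = as_harmonized(
        [_exp(sx, gamma, "exposure", cfg.n_x), _exp(sm, gamma_m, "mediator", med.n_m)],
        _exp(sy, Gamma, "outcome", cfg.n_y),
    )
    truth = SimTruth(
        config=cfg, gamma=gamma, alpha=alpha, pathway_label=labels,
        beta=med.total, maf=maf, snp_ids=snp,
        total=med.total, direct=med.theta_direct, indirect=med.indirect,
        extra={"eta": eta, "gamma_m": gamma_m},
    )
    return ds_xy, ds_xm, ds_my, ds_xmy, truth


@dataclass(frozen=True)
class DrugTargetSimConfig:
    """Cis-region fixture for the inhibition-proxy constructor."""

    p: int = 48
    block_size: int = 4
    within_block_r2: float = 0.6
    concordant_fraction: float = 0.5  # expression and biomarker move together
    beta_drug: float = -0.3  # effect of inhibition on the outcome (log-odds)
    eqtl_effect_sd: float = 0.3
    biomarker_effect_mean: float = 0.02
    biomarker_effect_sd: float = 0.005
    n_eqtl: int = 500
    n_biomarker: int = 45_000
    n_outcome: int = 15_000
    maf_range: tuple = (0.1, 0.5)
    seed: int = 0


def simulate_drug_target(cfg: DrugTargetSimConfig):
    """Generate (eqtl, biomarker, outcome, ld, truth) for the drug-target arm.

    A blocked cis region (constant within-block r2, zero between) with
    lead eQTLs of mixed sign; a planted fraction of SNPs is concordant
    (the expression-raising allele raises the biomarker), so the
    expression-lowering orientation lowers the biomarker and the SNP
    survives the sign filter.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    snp = np.array([f"cis{i + 1}" for i in range(p)], dtype=object)
    ea, oa = _alleles(p, rng)
    maf = rng.uniform(*cfg.maf_range, p)

    # LD: block-diagonal r2
    r2 = np.zeros((p, p))
    for start in range(0, p, cfg.block_size):
        stop = min(start + cfg.block_size, p)
        r2[start:stop, start:stop] = cfg.within_block_r2
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(list(snp), r2)

    expr_sign = rng.choice([-1.0, 1.0], p)
    expr_mag = np.abs(rng.normal(cfg.eqtl_effect_sd, cfg.eqtl_effect_sd / 4, p)) + 0.05
    expr_beta = expr_sign * expr_mag
    s_eqtl = _se_from_n(maf, cfg.n_eqtl)
    eqtl = _table(snp, ea, oa, maf, expr_beta, s_eqtl, cfg.n_eqtl, "gene_expression")

    concordant = rng.random(p) < cfg.concordant_fraction
    bio_mag = np.abs(rng.normal(cfg.biomarker_effect_mean, cfg.biomarker_effect_sd, p)) + 1e-4
    # concordant: biomarker moves with expression; discordant: against it
    bio_beta = np.where(concordant, expr_sign, -expr_sign) * bio_mag
    s_bio = _se_from_n(maf, cfg.n_biomarker)
    biomarker = _table(snp, ea, oa, maf, bio_beta, s_bio, cfg.n_biomarker, "biomarker")

    s_out = _se_from_n(maf, cfg.n_outcome)
    inhibition = -expr_beta  # effect of each effect allele on inhibition
    Gamma = cfg.beta_drug * inhibition + s_out * rng.standard_normal(p)
    outcome = _table(snp, ea, oa, maf, Gamma, s_out, cfg.n_outcome, "outcome")

    truth = SimTruth(
        config=None, gamma=expr_beta, alpha=np.zeros(p),
        pathway_label=np.where(concordant, "concordant", "discordant").astype(object),
        beta=cfg.beta_drug, maf=maf, snp_ids=snp,
        extra={"concordant": concordant, "drug_config": cfg},
    )
    return eqtl, biomarker, outcome, ld, truth


def simulate_individual_logistic(
    n: int = 5000, maf: float = 0.3, intercept: float = -2.0,
    beta_g: float = 0.2, seed: int = 0,
):
    """Tiny individual-level logistic GWAS for one SNP (scale sanity check).

    Draws genotypes Binomial(2, maf), binary outcomes from a logistic
    model, and returns the fitted per-allele log-odds ratio and SE from
    statsmodels. Confirms that the summary-scale generator's 'log-odds
    per allele' convention matches what a logistic GWAS would report.
    """
    import statsmodels.api as sm

    if n > 20_000:
        raise ValidationError("individual-level generator is capped at n = 20,000")
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, n)
    prob = 1.0 / (1.0 + np.exp(-(intercept + beta_g * g)))
    y = rng.binomial(1, prob)
    X = sm.add_constant(g.astype(float))
    fit = sm.Logit(y, X).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1])
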