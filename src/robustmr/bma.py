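"""Bayesian model averaging over instrument-inclusion vectors (BESIDE-MR).

A Metropolis-within-Gibbs sampler explores the joint posterior of the
causal effect(s), an overdispersion variance tau^2, and a per-SNP
inclusion indicator. An included SNP j contributes the normal
likelihood of Gamma_hat_j at beta_c * gamma_hat_j with variance
sigma_yj^2 + beta_c^2 sigma_xj^2 + tau^2 for its component c; excluded
SNPs contribute nothing. The inclusion prior p(I) proportional to
exp(lambda * sum I_j) tilts the average model size: lambda > 0 favors
inclusion, lambda < 0 parsimony. The per-SNP posterior probability of
inclusion (PPI) gauges each instrument's compatibility with a shared
causal effect — pleiotropic outliers are excluded often and earn a low
PPI.

With two components the causal effects are kept ordered
(beta_1 < beta_2) to resolve label switching, and a reassignment move
shuttles included SNPs between components. Chains are reproducible
bit-for-bit from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MREstimate, _wald
from .exceptions import RobustMRError, ValidationError
from .sumstats import HarmonizedDataset

BETA_PRIOR_SD = 10.0
TAU_HALF_NORMAL_SCALE = 0.5
MIN_MODEL_SIZE = 2
DEFAULT_ITERATIONS = 50_000
DEFAULT_BURN_IN = 10_000
_LOG2PI = np.log(2 * np.pi)


@dataclass
class PosteriorSample:
    """Raw MCMC draws from the instrument-averaging posterior."""

    beta_draws: np.ndarray  # (iterations, n_components)
    tau2_draws: np.ndarray  # (iterations,)
    assign_draws: np.ndarray  # (iterations, p) int8; 0 = excluded, 1..C = component
    n_components: int
    lam: float
    acceptance_rates: dict
    seed: int
    burn_in: int
    snp_ids: np.ndarray

    def kept(self):
        return (
            self.beta_draws[self.burn_in:],
            self.tau2_draws[self.burn_in:],
            self.assign_draws[self.burn_in:],
        )

    def to_frame(self) -> pd.DataFrame:
        """Draws as a delimited-friendly table (for external convergence tooling)."""
        cols = {"iteration": np.arange(len(self.tau2_draws))}
        for c in range(self.n_components):
            cols[f"beta{c + 1}"] = self.beta_draws[:, c]
        cols["tau2"] = self.tau2_draws
        cols["inclusion_bitmask"] = [
            "".join(str(int(a > 0)) for a in row) for row in self.assign_draws
        ]
        return pd.DataFrame(cols)


@dataclass
class PosteriorSummary:
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    credible_low: np.ndarray
    credible_high: np.ndarray
    ppi: np.ndarray
    mean_model_size: float
    ess: np.ndarray
    component_assignment: np.ndarray  # modal component per SNP (0 = mostly excluded)
    snp_ids: np.ndarray


def _loglik_terms(G, g, sG2, sg2, beta, tau2):
    var = sG2 + beta * beta * sg2 + tau2
    return -0.5 * (_LOG2PI + np.log(var) + (G - beta * g) ** 2 / var)


def run_beside(
    ds: HarmonizedDataset,
    n_components: int = 1,
    lam: float = 0.0,
    iterations: int = DEFAULT_ITERATIONS,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
    fix_inclusion: bool = False,
) -> PosteriorSample:
    """Run the Metropolis-within-Gibbs sampler.

    Priors: beta_c ~ N(0, 10^2); tau ~ half-normal(0.5); inclusion
    p(I) propto exp(lambda * sum I_j), minimum model size 2 per
    component. Moves per sweep: one inclusion flip (suppressed by
    ``fix_inclusion``), a random-walk update of each beta (step sizes
    adapted into an acceptance band during burn-in only), a tau update,
    and — with two components — one reassignment of an included SNP.
    Fixed seed implies bit-identical draws.
    """
    if ds.n_exposures != 1:
        raise ValueError("BESIDE-MR operates on a single exposure")
    p = ds.n_snps
    C = int(n_components)
    if C not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if p < 4:
        raise RobustMRError(
            f"only {p} SNPs: at least 4 instruments are needed for "
            "model averaging (and a two-component fit needs 2 per component)"
        )
    if C == 2 and p < 2 * MIN_MODEL_SIZE:
        raise RobustMRError("two components need at least 2 SNPs each")
    if iterations <= burn_in:
        raise ValidationError("iterations must exceed burn_in")

    rng = np.random.default_rng(seed)
    g, sg = ds.single_exposure()
    G, sG = ds.outcome_beta, ds.outcome_se
    sG2, sg2 = sG**2, sg**2

    # initial state: all SNPs included, components split by residual sign
    betas = np.sort(rng.normal(0.0, 0.1, size=C))
    tau = 0.1
    assign = np.ones(p, dtype=np.int8)
    if C == 2:
        assign[rng.permutation(p)[: p // 2]] = 2

    ll = np.zeros(p)  # per-SNP log-likelihood contribution (0 when excluded)
    def _refresh():
        for c in range(1, C + 1):
            m = assign == c
            ll[m] = _loglik_terms(G[m], g[m], sG2[m], sg2[m], betas[c - 1], tau * tau)
        ll[assign == 0] = 0.0

    _refresh()

    def _log_prior_beta(b):
        return -0.5 * (b / BETA_PRIOR_SD) ** 2

    def _log_prior_tau(t):
        return -0.5 * (t / TAU_HALF_NORMAL_SCALE) ** 2

    steps_beta = np.full(C, 0.05)
    step_tau = 0.05
    acc = {"flip": [0, 0], "beta": [0, 0], "tau": [0, 0], "reassign": [0, 0]}

    beta_draws = np.empty((iterations, C))
    tau2_draws = np.empty(iterations)
    assign_draws = np.empty((iterations, p), dtype=np.int8)

    window = {"beta": np.zeros(C), "tau": 0, "count": 0}
    ADAPT_EVERY = 200

    for it in range(iterations):
        # --- inclusion flip ---
        if not fix_inclusion:
            j = int(rng.integers(p))
            cur = assign[j]
            if cur > 0:
                size_c = int(np.sum(assign == cur))
                if size_c > MIN_MODEL_SIZE:
                    acc["flip"][1] += 1
                    # removing j: the reverse move re-adds it choosing among C components
                    log_alpha = -ll[j] - lam - (np.log(C) if C == 2 else 0.0)
                    if np.log(rng.random()) < log_alpha:
                        assign[j] = 0
                        ll[j] = 0.0
                        acc["flip"][0] += 1
                else:
                    acc["flip"][1] += 1  # proposal rejected by the size floor
            else:
                c_new = 1 if C == 1 else int(rng.integers(1, C + 1))
                new_ll = float(
                    _loglik_terms(G[j], g[j], sG2[j], sg2[j], betas[c_new - 1], tau * tau)
                )
                acc["flip"][1] += 1
                log_alpha = new_ll + lam + (np.log(C) if C == 2 else 0.0)
                if np.log(rng.random()) < log_alpha:
                    assign[j] = c_new
                    ll[j] = new_ll
                    acc["flip"][0] += 1

        # --- beta updates ---
        for c in range(1, C + 1):
            prop = betas[c - 1] + steps_beta[c - 1] * rng.normal()
            acc["beta"][1] += 1
            ordered = True
            if C == 2:
                trial = betas.copy()
                trial[c - 1] = prop
                ordered = trial[0] < trial[1]
            if ordered:
                m = assign == c
                new_terms = _loglik_terms(G[m], g[m], sG2[m], sg2[m], prop, tau * tau)
                log_alpha = (
                    float(np.sum(new_terms) - np.sum(ll[m]))
                    + _log_prior_beta(prop)
                    - _log_prior_beta(betas[c - 1])
                )
                if np.log(rng.random()) < log_alpha:
                    betas[c - 1] = prop
                    ll[m] = new_terms
                    acc["beta"][0] += 1
                    window["beta"][c - 1] += 1

        # --- tau update ---
        prop_tau = tau + step_tau * rng.normal()
        acc["tau"][1] += 1
        if prop_tau >= 0:
            new_ll = np.zeros(p)
            for c in range(1, C + 1):
                m = assign == c
                new_ll[m] = _loglik_terms(
                    G[m], g[m], sG2[m], sg2[m], betas[c - 1], prop_tau * prop_tau
                )
            inc = assign > 0
            log_alpha = (
                float(np.sum(new_ll[inc]) - np.sum(ll[inc]))
                + _log_prior_tau(prop_tau)
                - _log_prior_tau(tau)
            )
            if np.log(rng.random()) < log_alpha:
                tau = prop_tau
                ll[inc] = new_ll[inc]
                acc["tau"][0] += 1
                window["tau"] += 1

        # --- reassignment (two components) ---
        if C == 2:
            included = np.flatnonzero(assign > 0)
            if len(included):
                j = int(rng.choice(included))
                c_old = assign[j]
                c_new = 3 - c_old
                if int(np.sum(assign == c_old)) > MIN_MODEL_SIZE:
                    acc["reassign"][1] += 1
                    new_ll = float(
                        _loglik_terms(G[j], g[j], sG2[j], sg2[j], betas[c_new - 1], tau * tau)
                    )
                    if np.log(rng.random()) < new_ll - ll[j]:
                        assign[j] = c_new
                        ll[j] = new_ll
                        acc["reassign"][0] += 1

        # --- adaptation during burn-in only ---
        if it < burn_in and (it + 1) % ADAPT_EVERY == 0:
            rates = window["beta"] / ADAPT_EVERY
            steps_beta[rates > 0.6] *= 1.4
            steps_beta[rates < 0.15] *= 0.7
            tau_rate = window["tau"] / ADAPT_EVERY
            if tau_rate > 0.6:
                step_tau *= 1.4
            elif tau_rate < 0.15:
                step_tau *= 0.7
            window["beta"][:] = 0
            window["tau"] = 0

        beta_draws[it] = betas
        tau2_draws[it] = tau * tau
        assign_draws[it] = assign

    rates = {
        k: (a / n if n else np.nan) for k, (a, n) in acc.items() if n or k in ("flip",)
    }
    return PosteriorSample(
        beta_draws=beta_draws,
        tau2_draws=tau2_draws,
        assign_draws=assign_draws,
        n_components=C,
        lam=lam,
        acceptance_rates=rates,
        seed=seed,
        burn_in=burn_in,
        snp_ids=ds.snp_ids,
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var() + 1e-300)
    s = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += 2 * acf[k]
    return float(n / max(s, 1.0))


def summarize(ps: PosteriorSample) -> PosteriorSummary:
    """Posterior means, central 95% credible intervals, PPI, and ESS diagnostics."""
    beta, tau2, assign = ps.kept()
    if len(beta) == 0:
        raise ValidationError("no draws beyond burn_in")
    included = assign > 0
    ppi = included.mean(axis=0)
    mean_model_size = float(included.sum(axis=1).mean())
    lo, hi = np.quantile(beta, [0.025, 0.975], axis=0)
    # modal component per SNP among included draws
    comp = np.zeros(assign.shape[1], dtype=int)
    for j in range(assign.shape[1]):
        counts = np.bincount(assign[:, j], minlength=ps.n_components + 1)
        comp[j] = int(np.argmax(counts[1:]) + 1) if counts[1:].sum() else 0
        if ppi[j] < 0.5:
            comp[j] = 0
    return PosteriorSummary(
        beta_mean=beta.mean(axis=0),
        beta_sd=beta.std(axis=0, ddof=1),
        credible_low=np.atleast_1d(lo),
        credible_high=np.atleast_1d(hi),
        ppi=ppi,
        mean_model_size=mean_model_size,
        ess=np.array([_ess(beta[:, c]) for c in range(beta.shape[1])]),
        component_assignment=comp,
        snp_ids=ps.snp_ids,
    )


def beside_dl(ds: HarmonizedDataset, ps: PosteriorSample, ppi_threshold: float = 0.5) -> MREstimate:
    """Profile fit on the PPI-filtered instrument subset with a DerSimonian-Laird SE.

    An interpretation of a 'DL' summary for model-averaged MR: keep
    SNPs with PPI > threshold, estimate beta by inverse-variance
    weighting with a DerSimonian-Laird between-SNP variance added to
    each weight. Flagged as an interpretation in ``diagnostics``.
    """
    summ = summarize(ps)
    keep = summ.ppi > ppi_threshold
    if keep.sum() < 2:
        raise RobustMRError("fewer than 2 SNPs pass the PPI filter")
    sub = ds.subset(np.asarray(keep))
    g, sg = sub.single_exposure()
    G, sG = sub.outcome_beta, sub.outcome_se
    ratio = G / g
    var0 = sG**2 / g**2  # first-order ratio variance
    w0 = 1.0 / var0
    beta0 = float(np.sum(w0 * ratio) / np.sum(w0))
    q = float(np.sum(w0 * (ratio - beta0) ** 2))
    k = len(ratio)
    denom = float(np.sum(w0) - np.sum(w0**2) / np.sum(w0))
    tau2_dl = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w = 1.0 / (var0 + tau2_dl)
    beta = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    lo, hi, pval = _wald(beta, se)
    return MREstimate(
        beta, se, lo, hi, pval, "BESIDE-DL", k, tau2=tau2_dl,
        scale=ds.meta.get("outcome_scale", "log_odds"),
        diagnostics={
            "interpretation": "DL-style overdispersion fit on the PPI>%.2f subset" % ppi_threshold,
            "ppi_threshold": ppi_threshold,
        },
    )
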