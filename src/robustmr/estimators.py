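"""Univariable causal-effect estimators for two-sample MR.

Notation: per SNP j, ``gamma_hat_j`` / ``sigma_xj`` are the SNP-exposure
estimate and SE, ``Gamma_hat_j`` / ``sigma_yj`` the SNP-outcome pair.
The target is the causal effect beta (log-odds units for a binary
outcome), estimated by

* :func:`ivw` — classical inverse-variance weighting, equivalently the
  zero-intercept WLS regression of Gamma_hat on gamma_hat with weights
  1/sigma_y^2; biased toward the null under weak instruments and
  winner's curse.
* :func:`divw` — debiased IVW, which subtracts the measurement-error
  term sigma_x^2 from each squared instrument strength, restoring
  consistency with many weak instruments. Its validity is governed by
  the effective instrument-strength condition :func:`condition_number`.
* :func:`raps` — the robust adjusted profile score: beta maximizes
  -sum_j rho(t_j), t_j = (Gamma_hat_j - beta*gamma_hat_j) /
  sqrt(sigma_yj^2 + beta^2 sigma_xj^2 + tau^2), with rho squared-error,
  Huber, or Tukey biweight. Optional overdispersion tau^2 absorbs
  balanced horizontal pleiotropy and is solved jointly from the
  consistency-corrected second estimating equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateInstrumentsError,
    InstrumentStrengthError,
    WeakInstrumentWarning,
)
from .losses import Loss, get_loss
from .sumstats import HarmonizedDataset

Z95 = stats.norm.ppf(0.975)
DEFAULT_CONDITION_FLOOR = 20.0


@dataclass
class MREstimate:
    """A univariable causal-effect estimate with Wald uncertainty."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str
    n_snps: int
    tau2: float | None = None
    converged: bool = True
    condition: float | None = None
    scale: str = "log_odds"
    diagnostics: dict | None = None

    def __post_init__(self):
        if self.converged:
            if not self.se > 0:
                raise ValueError("converged estimate must have positive SE")
            if not (self.ci_low <= self.beta <= self.ci_high):
                raise ValueError("CI must bracket the point estimate")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


def _wald(beta: float, se: float) -> tuple[float, float, float]:
    z = beta / se
    return beta - Z95 * se, beta + Z95 * se, 2 * stats.norm.sf(abs(z))


def or_from_beta(est: MREstimate) -> tuple[float, float, float]:
    """Causal odds ratio and 95% CI from a log-odds-scale estimate."""
    return float(np.exp(est.beta)), float(np.exp(est.ci_low)), float(np.exp(est.ci_high))


def _univariable(ds: HarmonizedDataset):
    if ds.n_exposures != 1:
        raise ValueError("univariable estimator requires a single exposure")
    g, sg = ds.single_exposure()
    return g, sg, ds.outcome_beta, ds.outcome_se


# ---------------------------------------------------------------------------
# IVW and debiased IVW
# ---------------------------------------------------------------------------


def ivw(ds: HarmonizedDataset, random_effects: bool = True) -> MREstimate:
    """Classical inverse-variance-weighted estimate.

    ``random_effects`` applies the multiplicative random-effects SE
    inflation max(1, sqrt(Q/(p-1))) when p >= 2.
    """
    g, _sg, G, sG = _univariable(ds)
    w = 1.0 / sG**2
    denom = float(np.sum(g * g * w))
    if denom == 0:
        raise DegenerateInstrumentsError("all instrument strengths are zero")
    beta = float(np.sum(g * G * w) / denom)
    se = denom**-0.5
    method = "IVW"
    if random_effects and len(g) >= 2:
        q = float(np.sum(w * (G - beta * g) ** 2))
        se *= max(1.0, np.sqrt(q / (len(g) - 1)))
    lo, hi, p = _wald(beta, se)
    return MREstimate(beta, se, lo, hi, p, method, len(g),
                      scale=ds.meta.get("outcome_scale", "log_odds"))


def condition_number(ds: HarmonizedDataset) -> float:
    """Effective instrument strength kappa = [sum_j (gamma_hat_j^2 - sigma_xj^2) / sigma_xj^2] / sqrt(p).

    Governs debiased-IVW validity; may be negative for null instruments
    and is reported as-is.
    """
    g, sg, _G, _sG = _univariable(ds)
    with np.errstate(divide="ignore"):
        return float(np.sum((g * g - sg * sg) / (sg * sg)) / np.sqrt(len(g)))


def divw(ds: HarmonizedDataset, condition_floor: float = DEFAULT_CONDITION_FLOOR) -> MREstimate:
    """Debiased IVW: beta = sum(g*G/sY^2) / sum((g^2 - sx^2)/sY^2).

    SE from the estimating-equation sandwich with per-SNP score variance
    [(g^2 - sx^2)(sY^2 + b^2 sx^2) + sx^2 sY^2 + 2 b^2 sx^4] / sY^4.
    Warns when the condition measure falls below ``condition_floor``.
    """
    g, sg, G, sG = _univariable(ds)
    w = 1.0 / sG**2
    denom = float(np.sum((g * g - sg * sg) * w))
    if denom <= 0:
        raise InstrumentStrengthError(
            "debiased-IVW denominator <= 0: instruments carry no net strength "
            f"(sum (gamma^2 - sigma_x^2)/sigma_y^2 = {denom:.3g}); "
            "consider more/stronger instruments"
        )
    beta = float(np.sum(g * G * w) / denom)
    v = ((g * g - sg * sg) * (sG**2 + beta**2 * sg**2) + sg**2 * sG**2 + 2 * beta**2 * sg**4) / sG**4
    se = float(np.sqrt(np.sum(v)) / denom)
    kappa = condition_number(ds)
    if kappa < condition_floor:
        warnings.warn(
            f"dIVW condition {kappa:.2f} below floor {condition_floor:g}: "
            "weak instruments, estimate may be unstable",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    lo, hi, p = _wald(beta, se)
    return MREstimate(beta, se, lo, hi, p, "dIVW", len(g), condition=kappa,
                      scale=ds.meta.get("outcome_scale", "log_odds"))


# ---------------------------------------------------------------------------
# RAPS
# ---------------------------------------------------------------------------


def _residuals(beta, tau2, g, sg, G, sG):
    s = np.sqrt(sG**2 + beta**2 * sg**2 + tau2)
    return (G - beta * g) / s, s


def _objective(beta, tau2, g, sg, G, sG, loss: Loss) -> float:
    t, _ = _residuals(beta, tau2, g, sg, G, sG)
    return float(np.sum(loss.rho(t)))


def _grad_beta(beta, tau2, g, sg, G, sG, loss: Loss) -> float:
    t, s = _residuals(beta, tau2, g, sg, G, sG)
    dt = -g / s - t * beta * sg**2 / s**2
    return float(np.sum(loss.psi(t) * dt))


def _minimize_beta(start, tau2, g, sg, G, sG, loss: Loss,
                   span: float = 2.0, grid_lo: float = -5.0, grid_hi: float = 5.0,
                   grid_step: float = 1e-3):
    """Safeguarded scalar minimization of the profile objective in beta.

    Bounded local search around ``start`` with Newton polish; falls back
    to a full grid scan when the local search lands on its bounds.
    Returns (beta, converged_flag).
    """
    obj = lambda b: _objective(b, tau2, g, sg, G, sG, loss)

    def _local(lo, hi):
        res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        return float(res.x)

    b = _local(start - span, start + span)
    if min(b - (start - span), (start + span) - b) < 1e-6:
        grid = np.arange(grid_lo, grid_hi + grid_step, grid_step)
        vals = np.array([obj(x) for x in grid]) if len(g) > 2000 else None
        if vals is None:
            # vectorized evaluation over the grid
            t = (G[:, None] - grid[None, :] * g[:, None]) / np.sqrt(
                sG[:, None] ** 2 + grid[None, :] ** 2 * sg[:, None] ** 2 + tau2
            )
            vals = loss.rho(t).sum(axis=0)
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        b = _local(lo, hi)
        if min(abs(b - grid_lo), abs(grid_hi - b)) < 2 * grid_step:
            return b, False
    # Newton polish with analytic gradient, numeric curvature
    for _ in range(4):
        gr = _grad_beta(b, tau2, g, sg, G, sG, loss)
        h = 1e-5 * max(1.0, abs(b))
        hess = (_grad_beta(b + h, tau2, g, sg, G, sG, loss)
                - _grad_beta(b - h, tau2, g, sg, G, sG, loss)) / (2 * h)
        if hess <= 0 or not np.isfinite(hess):
            break
        step = gr / hess
        if not np.isfinite(step) or abs(step) > span:
            break
        if obj(b - step) <= obj(b):
            b -= step
        if abs(step) < 1e-14:
            break
    scale = max(1.0, float(np.sum(np.abs(g) / sG)))
    converged = abs(_grad_beta(b, tau2, g, sg, G, sG, loss)) < 1e-5 * scale
    return b, converged


def _tau2_equation(tau2, beta, g, sg, G, sG, loss: Loss) -> float:
    t, s = _residuals(beta, tau2, g, sg, G, sG)
    w = 1.0 / s**2
    return float(np.sum((loss.psi(t) * t - loss.delta) * w))


def _solve_tau2(beta, g, sg, G, sG, loss: Loss) -> float:
    f0 = _tau2_equation(0.0, beta, g, sg, G, sG, loss)
    if f0 <= 0:
        return 0.0
    hi = float(np.median(sG**2))
    for _ in range(60):
        if _tau2_equation(hi, beta, g, sg, G, sG, loss) < 0:
            break
        hi *= 2.0
    else:
        return hi
    return float(optimize.brentq(
        lambda x: _tau2_equation(x, beta, g, sg, G, sG, loss), 0.0, hi, xtol=1e-14
    ))


def _raps_scores(theta, g, sg, G, sG, loss: Loss, overdispersion: bool) -> np.ndarray:
    """Per-SNP estimating-equation contributions, shape (p, n_params)."""
    beta = theta[0]
    tau2 = theta[1] if overdispersion else 0.0
    t, s = _residuals(beta, tau2, g, sg, G, sG)
    dt = -g / s - t * beta * sg**2 / s**2
    cols = [loss.psi(t) * dt]
    if overdispersion:
        cols.append((loss.psi(t) * t - loss.delta) / s**2)
    return np.column_stack(cols)


def _sandwich_se(theta, g, sg, G, sG, loss: Loss, overdispersion: bool) -> float:
    m = _raps_scores(theta, g, sg, G, sG, loss, overdispersion)
    bread_dim = m.shape[1]
    A = np.zeros((bread_dim, bread_dim))
    for k in range(bread_dim):
        h = 1e-6 * max(1.0, abs(theta[k]))
        tp = np.array(theta, dtype=float)
        tm = np.array(theta, dtype=float)
        tp[k] += h
        tm[k] -= h
        A[:, k] = (
            _raps_scores(tp, g, sg, G, sG, loss, overdispersion).sum(axis=0)
            - _raps_scores(tm, g, sg, G, sG, loss, overdispersion).sum(axis=0)
        ) / (2 * h)
    B = m.T @ m
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv.T
    return float(np.sqrt(cov[0, 0]))


def raps(
    ds: HarmonizedDataset,
    loss: str | Loss = "tukey",
    overdispersion: bool = False,
    start: float | None = None,
) -> MREstimate:
    """Robust adjusted profile score estimate.

    beta maximizes -sum_j rho(t_j(beta, tau2)); with ``overdispersion``
    tau2 >= 0 is solved jointly from
    sum_j [psi(t_j) t_j - E(psi(Z)Z)] / s_j^2 = 0 by alternating with
    the beta step. SEs come from the M-estimation sandwich. The
    optimizer starts from the dIVW estimate (consistent under weak
    instruments) with a grid-scan fallback; ``converged`` is honest.
    """
    lossf = get_loss(loss)
    g, sg, G, sG = _univariable(ds)
    if start is None:
        try:
            start = divw(ds, condition_floor=-np.inf).beta
        except InstrumentStrengthError:
            start = ivw(ds).beta
    tau2 = 0.0
    beta, conv = _minimize_beta(start, tau2, g, sg, G, sG, lossf)
    if overdispersion:
        for _ in range(100):
            tau2_new = _solve_tau2(beta, g, sg, G, sG, lossf)
            beta_new, conv = _minimize_beta(beta, tau2_new, g, sg, G, sG, lossf, span=0.5)
            done = abs(beta_new - beta) < 1e-11 and abs(tau2_new - tau2) < 1e-13
            beta, tau2 = beta_new, tau2_new
            if done:
                break
        else:
            conv = False
    theta = [beta, tau2] if overdispersion else [beta]
    try:
        se = _sandwich_se(theta, g, sg, G, sG, lossf, overdispersion)
        if not np.isfinite(se) or se <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        conv, se = False, np.nan
    method = f"RAPS-{lossf.name}"
    if not conv:
        return MREstimate(beta, se, np.nan, np.nan, np.nan, method, len(g),
                          tau2=tau2 if overdispersion else None, converged=False,
                          scale=ds.meta.get("outcome_scale", "log_odds"),
                          diagnostics={"grad": _grad_beta(beta, tau2, g, sg, G, sG, lossf)})
    lo, hi, p = _wald(beta, se)
    return MREstimate(beta, se, lo, hi, p, method, len(g),
                      tau2=tau2 if overdispersion else None,
                      scale=ds.meta.get("outcome_scale", "log_odds"))
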