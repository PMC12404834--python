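"""Robust profile-likelihood machinery for pleiotropic-pathway discovery.

The robust profile objective L(beta) = -sum_j rho(t_j(beta)), with
standardized residuals t_j = (Gamma_hat_j - beta*gamma_hat_j) /
sqrt(sigma_yj^2 + beta^2 sigma_xj^2), is evaluated on a beta grid.
Under a single valid causal pathway the curve has one mode near the
causal effect. Correlated pleiotropy (a subset of instruments acting
through a shared confounder, violating InSIDE) produces additional
modes, each marking an apparent effect along a pathway; the SNPs whose
residuals are small at a mode are its *markers*. A multimodal curve
with a secondary peak near zero is the classic signature of a reversed
causal direction.

Multivariable extension: with K exposures, t_j(b) =
(Gamma_hat_j - sum_k b_k gamma_hat_jk) / sqrt(sigma_yj^2 +
sum_k b_k^2 sigma_xjk^2) under independent exposure measurement
errors; the modified conditional Cochran's Q = sum_j t_j^2 is
chi-square with p - K degrees of freedom under instrument validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .estimators import MREstimate, Z95
from .exceptions import (
    ConvergenceError,
    RobustMRError,
    UnderIdentifiedError,
)
from .losses import Loss, get_loss
from .sumstats import HarmonizedDataset

DEFAULT_GRID = (-2.0, 2.0, 0.001)
DEFAULT_MIN_SEPARATION = 0.05
DEFAULT_MIN_PROMINENCE = 2.0
DEFAULT_MARKER_CUTOFF = 1.0


@dataclass
class Mode:
    beta: float
    objective: float
    curvature: float  # second derivative of the objective at the mode (<= 0)


@dataclass
class ProfileCurve:
    grid: np.ndarray
    loglik: np.ndarray
    modes: list  # all refined strict local maxima, unfiltered
    residuals_at_mode: dict  # mode beta -> per-SNP standardized residuals
    loss: str = "tukey"

    def __post_init__(self):
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class ModeSet:
    """Filtered modes (objective-descending) plus the direction diagnostic."""

    modes: list
    near_zero_flag: bool

    def __iter__(self):
        return iter(self.modes)

    def __len__(self):
        return len(self.modes)


def _mv_residuals(betas: np.ndarray, ds: HarmonizedDataset, tau2: float = 0.0):
    betas = np.asarray(betas, dtype=float).ravel()
    fitted = ds.exposure_beta @ betas
    var = ds.outcome_se**2 + (ds.exposure_se**2) @ (betas**2) + tau2
    s = np.sqrt(var)
    return (ds.outcome_beta - fitted) / s, s


def _mv_objective(betas, ds, loss: Loss) -> float:
    t, _ = _mv_residuals(betas, ds)
    return float(np.sum(loss.rho(t)))


# ---------------------------------------------------------------------------
# Profile curve and modes
# ---------------------------------------------------------------------------


def robust_profile(
    ds: HarmonizedDataset,
    grid_spec: tuple = DEFAULT_GRID,
    loss: str | Loss = "tukey",
) -> ProfileCurve:
    """Evaluate the robust profile objective on a beta grid (tau2 = 0).

    ``grid_spec`` is (lo, hi, step) or an explicit increasing array.
    Each gridded local maximum is refined by bounded scalar
    optimization within its bracketing cells.
    """
    if ds.n_exposures != 1:
        raise ValueError("robust_profile requires a single exposure")
    lossf = get_loss(loss)
    if isinstance(grid_spec, np.ndarray):
        grid = np.asarray(grid_spec, dtype=float)
    else:
        lo, hi, step = grid_spec
        grid = np.arange(lo, hi + step / 2, step)
    g, sg = ds.single_exposure()
    G, sG = ds.outcome_beta, ds.outcome_se
    t = (G[:, None] - grid[None, :] * g[:, None]) / np.sqrt(
        sG[:, None] ** 2 + grid[None, :] ** 2 * sg[:, None] ** 2
    )
    loglik = -lossf.rho(t).sum(axis=0)

    interior = np.flatnonzero(
        (loglik[1:-1] > loglik[:-2]) & (loglik[1:-1] >= loglik[2:])
    ) + 1
    if len(interior) == 0:
        raise RobustMRError(
            "no interior local maximum bracketed by the grid; use a finer "
            "step or a wider range"
        )

    obj = lambda b: -_mv_objective([b], ds, lossf)
    modes = []
    residuals = {}
    seen = []
    for i in interior:
        res = optimize.minimize_scalar(
            lambda b: _mv_objective([b], ds, lossf),
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        b = float(res.x)
        if any(abs(b - s) < 1e-8 for s in seen):
            continue
        seen.append(b)
        h = max(1e-5, 1e-4 * abs(b))
        curv = (obj(b + h) - 2 * obj(b) + obj(b - h)) / h**2
        modes.append(Mode(beta=b, objective=obj(b), curvature=float(curv)))
        tres, _ = _mv_residuals([b], ds)
        residuals[b] = tres
    modes.sort(key=lambda m: m.beta)
    return ProfileCurve(grid=grid, loglik=loglik, modes=modes,
                        residuals_at_mode=residuals, loss=lossf.name)


def detect_modes(
    curve: ProfileCurve,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    near_zero_tol: float | None = None,
) -> ModeSet:
    """Filter profile-curve maxima by prominence and pairwise separation.

    Prominence is the objective drop to the higher neighboring valley
    (computed on the gridded curve). Surviving modes are ordered by
    objective descending. The direction diagnostic flags a multimodal
    curve with any mode within ``near_zero_tol`` (default
    ``min_separation``) of zero — the signature of a misspecified
    (reversed) causal direction.
    """
    if near_zero_tol is None:
        near_zero_tol = min_separation
    peaks, props = signal.find_peaks(curve.loglik, prominence=min_prominence)
    kept = []
    for i in peaks:
        b_grid = curve.grid[i]
        if not curve.modes:
            continue
        nearest = min(curve.modes, key=lambda m: abs(m.beta - b_grid))
        step = np.median(np.diff(curve.grid))
        if abs(nearest.beta - b_grid) <= 2 * step + 1e-12:
            kept.append(nearest)
    # dedupe, order by objective, enforce separation greedily
    kept = sorted({id(m): m for m in kept}.values(), key=lambda m: -m.objective)
    final = []
    for m in kept:
        if all(abs(m.beta - f.beta) >= min_separation for f in final):
            final.append(m)
    flag = len(final) >= 2 and any(abs(m.beta) <= near_zero_tol for m in final)
    return ModeSet(modes=final, near_zero_flag=flag)


def marker_snps(
    ds: HarmonizedDataset,
    mode_beta: float,
    residual_cutoff: float = DEFAULT_MARKER_CUTOFF,
) -> list:
    """SNP ids whose standardized residual at ``mode_beta`` is < cutoff in absolute value."""
    if not np.isfinite(mode_beta):
        raise ValueError("mode_beta must be finite")
    t, _ = _mv_residuals([mode_beta], ds)
    return [str(s) for s in ds.snp_ids[np.abs(t) < residual_cutoff]]


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------


@dataclass
class MVMREstimate:
    """Joint direct-effect estimates for K exposures."""

    betas: np.ndarray
    cov: np.ndarray
    pvalues: np.ndarray
    bonferroni_significant: np.ndarray
    q_stat: float
    q_df: int
    q_pvalue: float
    n_snps: int
    exposure_labels: list = field(default_factory=list)
    converged: bool = True

    @property
    def ses(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def ci(self, k: int) -> tuple[float, float]:
        se = self.ses[k]
        return float(self.betas[k] - Z95 * se), float(self.betas[k] + Z95 * se)


def mvmr_fit(ds: HarmonizedDataset, loss: str | Loss = "tukey") -> MVMREstimate:
    """Multivariable robust profile-score fit (K exposures jointly).

    betas maximize -sum_j rho(t_j(b)); cov is the inverse observed
    information (numerical Hessian of the objective) at the optimum.
    Per-exposure Wald p-values carry a Bonferroni flag at 0.05/K.
    """
    lossf = get_loss(loss)
    p, K = ds.n_snps, ds.n_exposures
    if p <= K:
        raise UnderIdentifiedError(f"{p} SNPs cannot identify {K} exposures")

    # exposures with an all-zero effect column are identified only through
    # the variance channel (a degenerate direction of the profile
    # objective): pin their coefficient at 0 and fit the reduced model
    X = ds.exposure_beta
    nonzero = np.abs(X).max(axis=0) > 0
    if not nonzero.any():
        raise UnderIdentifiedError("every exposure column is zero")
    ds_fit = ds if nonzero.all() else HarmonizedDataset(
        snp_ids=ds.snp_ids,
        exposure_beta=X[:, nonzero],
        exposure_se=ds.exposure_se[:, nonzero],
        outcome_beta=ds.outcome_beta,
        outcome_se=ds.outcome_se,
        meta=dict(ds.meta),
    )
    Kr = ds_fit.n_exposures
    Xr = ds_fit.exposure_beta
    w = 1.0 / ds.outcome_se**2
    XtW = Xr.T * w
    A = XtW @ Xr
    if np.linalg.cond(A) > 1e10:
        raise ConvergenceError("singular information: exposures are collinear")
    start = np.linalg.solve(A, XtW @ ds.outcome_beta)

    res = optimize.minimize(
        lambda b: _mv_objective(b, ds_fit, lossf),
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    res2 = optimize.minimize(
        lambda b: _mv_objective(b, ds_fit, lossf), res.x, method="BFGS",
        options={"gtol": 1e-10},
    )
    betas_r = res2.x if res2.fun <= res.fun else res.x
    converged = bool(res.success or res2.success)

    # observed information: numerical Hessian of sum rho(t_j)
    H = np.zeros((Kr, Kr))
    h = 1e-5 * np.maximum(1.0, np.abs(betas_r))
    for a in range(Kr):
        for b in range(a, Kr):
            ea = np.zeros(Kr)
            eb = np.zeros(Kr)
            ea[a] = h[a]
            eb[b] = h[b]
            fpp = _mv_objective(betas_r + ea + eb, ds_fit, lossf)
            fpm = _mv_objective(betas_r + ea - eb, ds_fit, lossf)
            fmp = _mv_objective(betas_r - ea + eb, ds_fit, lossf)
            fmm = _mv_objective(betas_r - ea - eb, ds_fit, lossf)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        cov_r = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular observed information at the optimum")
    if not np.all(np.isfinite(cov_r)) or np.any(np.diag(cov_r) <= 0):
        raise ConvergenceError("observed information not positive definite")
    cov_r = 0.5 * (cov_r + cov_r.T)

    betas = np.zeros(K)
    betas[nonzero] = betas_r
    cov = np.zeros((K, K))
    cov[np.ix_(nonzero, nonzero)] = cov_r
    ses_r = np.sqrt(np.diag(cov_r))
    pvalues = np.ones(K)
    pvalues[nonzero] = 2 * stats.norm.sf(np.abs(betas_r / ses_r))
    q, df, qp = conditional_q(ds, betas)
    return MVMREstimate(
        betas=np.asarray(betas, dtype=float),
        cov=cov,
        pvalues=pvalues,
        bonferroni_significant=pvalues < 0.05 / K,
        q_stat=q,
        q_df=df,
        q_pvalue=qp,
        n_snps=p,
        exposure_labels=list(ds.meta.get("exposure_labels", [])),
        converged=converged,
    )


def conditional_q(ds: HarmonizedDataset, betas) -> tuple[float, int, float]:
    """Modified conditional Cochran's Q = sum_j t_j(betas)^2, df = p - K."""
    betas = np.asarray(betas, dtype=float).ravel()
    if betas.shape[0] != ds.n_exposures:
        raise ValueError("betas length must equal the number of exposures")
    df = ds.n_snps - len(betas)
    if df < 1:
        raise UnderIdentifiedError("Q degrees of freedom < 1")
    t, _ = _mv_residuals(betas, ds)
    q = float(np.sum(t * t))
    return q, df, float(stats.chi2.sf(q, df))


# ---------------------------------------------------------------------------
# QQ diagnostic
# ---------------------------------------------------------------------------


@dataclass
class QQResult:
    table: pd.DataFrame  # theoretical_quantile, observed_t
    shapiro_stat: float
    shapiro_pvalue: float


def residual_qq(ds: HarmonizedDataset, est: MREstimate) -> QQResult:
    """Standard-normal QQ data for the standardized residuals at a fitted estimate.

    Under valid instruments and the InSIDE assumption the residuals are
    approximately standard normal; systematic departure flags
    uncorrected pleiotropy. A Shapiro-Wilk summary is attached.
    """
    tau2 = est.tau2 or 0.0
    g, sg = ds.single_exposure()
    s = np.sqrt(ds.outcome_se**2 + est.beta**2 * sg**2 + tau2)
    t = (ds.outcome_beta - est.beta * g) / s
    order = np.argsort(t)
    p = len(t)
    theo = stats.norm.ppf((np.arange(1, p + 1) - 0.5) / p)
    if np.ptp(t) > 0:
        sw = stats.shapiro(t)
        stat, pval = float(sw.statistic), float(sw.pvalue)
    else:
        stat, pval = np.nan, np.nan
    table = pd.DataFrame(
        {"SNP": ds.snp_ids[order], "theoretical_quantile": theo, "observed_t": t[order]}
    )
    return QQResult(table=table, shapiro_stat=stat, shapiro_pvalue=pval)
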