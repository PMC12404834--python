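"""Causal mediation by MR: difference-in-coefficients decomposition.

The total effect of the exposure on the outcome comes from a
univariable estimator on the exposure-outcome dataset; the direct
effect (bypassing the mediator) is the exposure's coefficient in a
multivariable fit that adjusts for the mediator's genetic effects; the
indirect effect is total - direct, exactly, and the proportion
mediated is indirect / total.

The default indirect-effect SE is the independence approximation
sqrt(se_total^2 + se_direct^2); a parametric bootstrap that jointly
resamples the summary estimates is available when the two fits share
data and the approximation is suspect. Both are reported when they
disagree by more than 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95, divw, ivw, raps
from .exceptions import RobustMRError, ValidationError
from .profile import MVMREstimate, mvmr_fit
from .sumstats import HarmonizedDataset

ESTIMATORS = {
    "ivw": lambda ds: ivw(ds),
    "divw": lambda ds: divw(ds),
    "raps-l2": lambda ds: raps(ds, loss="l2"),
    "raps-huber": lambda ds: raps(ds, loss="huber"),
    "raps-tukey": lambda ds: raps(ds, loss="tukey"),
}

PROPORTION_GUARD_MULTIPLIER = 2.0


@dataclass
class MediationResult:
    total: MREstimate
    direct_beta: float
    direct_se: float
    indirect_beta: float
    indirect_se: float
    indirect_ci: tuple
    indirect_pvalue: float
    proportion_mediated: float | None
    proportion_ci: tuple | None
    proportion_defined: bool
    mediator_label: str = ""
    indirect_se_bootstrap: float | None = None

    @property
    def direct_ci(self) -> tuple:
        return (self.direct_beta - Z95 * self.direct_se,
                self.direct_beta + Z95 * self.direct_se)


def total_effect(ds_xy: HarmonizedDataset, method: str = "raps-tukey") -> MREstimate:
    """Univariable total effect of the exposure on the outcome."""
    try:
        est = ESTIMATORS[method]
    except KeyError:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(ESTIMATORS)}")
    return est(ds_xy)


def direct_effect(ds_xmy: HarmonizedDataset, loss: str = "tukey") -> MVMREstimate:
    """Direct effect via multivariable MR adjusting for the mediator.

    ``ds_xmy`` must carry two exposures, the exposure of interest first
    and the mediator second; the first coefficient is the direct effect.
    """
    if ds_xmy.n_exposures != 2:
        raise ValidationError("direct_effect expects exposures {exposure, mediator}")
    return mvmr_fit(ds_xmy, loss=loss)


def mediate(
    total: MREstimate,
    direct_beta: float,
    direct_se: float,
    mediator_label: str = "",
    direct_scale: str | None = None,
    bootstrap_draws: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Difference-in-coefficients decomposition.

    indirect = total - direct (exact identity); indirect SE is the
    independence approximation, optionally supplemented by a normal
    parametric bootstrap (``bootstrap_draws`` > 0). The proportion
    mediated uses the delta method and is suppressed when
    |total.beta| < 2 * total.se (ratio CIs explode near a null total).
    """
    if direct_scale is not None and total.scale is not None and direct_scale != total.scale:
        raise RobustMRError(
            f"scale mismatch: total on {total.scale!r}, direct on {direct_scale!r}"
        )
    indirect = total.beta - direct_beta
    se_indep = float(np.sqrt(total.se**2 + direct_se**2))
    se_boot = None
    if bootstrap_draws > 0:
        rng = np.random.default_rng(seed)
        draws = rng.normal(total.beta, total.se, bootstrap_draws) - rng.normal(
            direct_beta, direct_se, bootstrap_draws
        )
        se_boot = float(draws.std(ddof=1))
    se = se_indep
    ci = (indirect - Z95 * se, indirect + Z95 * se)
    pval = 2 * stats.norm.sf(abs(indirect / se)) if se > 0 else np.nan

    defined = abs(total.beta) >= PROPORTION_GUARD_MULTIPLIER * total.se
    if defined:
        prop = indirect / total.beta
        # delta method for (T - D)/T = 1 - D/T with cov(T, D) = 0
        var_p = (direct_beta**2 / total.beta**4) * total.se**2 + direct_se**2 / total.beta**2
        sp = float(np.sqrt(var_p))
        prop_ci = (prop - Z95 * sp, prop + Z95 * sp)
    else:
        prop, prop_ci = None, None
    return MediationResult(
        total=total,
        direct_beta=float(direct_beta),
        direct_se=float(direct_se),
        indirect_beta=float(indirect),
        indirect_se=se,
        indirect_ci=ci,
        indirect_pvalue=float(pval),
        proportion_mediated=prop,
        proportion_ci=prop_ci,
        proportion_defined=defined,
        mediator_label=mediator_label,
        indirect_se_bootstrap=se_boot,
    )


def run_mediation(
    ds_xy: HarmonizedDataset,
    ds_xmy: HarmonizedDataset,
    method: str = "raps-tukey",
    mediator_label: str = "",
) -> MediationResult:
    """Convenience wrapper: total effect, MVMR direct effect, decomposition."""
    tot = total_effect(ds_xy, method=method)
    mv = direct_effect(ds_xmy)
    return mediate(
        tot,
        float(mv.betas[0]),
        float(mv.ses[0]),
        mediator_label=mediator_label or (
            mv.exposure_labels[1] if len(mv.exposure_labels) > 1 else ""
        ),
    )
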