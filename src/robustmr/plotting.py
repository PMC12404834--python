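"""Diagnostic figures: profile-likelihood curve and residual QQ plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def profile_plot(curve, path) -> None:
    """Robust profile objective over the beta grid with detected maxima marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.grid, curve.loglik, lw=1.2)
    for m in curve.modes:
        ax.axvline(m.beta, ls=":", lw=0.8, color="crimson")
    ax.set_xlabel(r"candidate causal effect $\beta$")
    ax.set_ylabel("robust profile objective")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(qq, path) -> None:
    """Standardized residuals against standard-normal quantiles."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    t = qq.table
    ax.scatter(t["theoretical_quantile"], t["observed_t"], s=12, alpha=0.7)
    lim = [t["theoretical_quantile"].min(), t["theoretical_quantile"].max()]
    ax.plot(lim, lim, color="grey", lw=0.8)
    ax.set_xlabel("theoretical N(0,1) quantile")
    ax.set_ylabel("standardized residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
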