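"""Robust loss functions for profile-score estimation.

Each loss is defined by rho (the objective contribution), psi = rho'
(the influence function), and the consistency constant
``delta = E[psi(Z) Z]`` for standard-normal Z, used by the
overdispersion estimating equation so that tau^2 is estimated without
bias under the correct model.

Tuning constants are the standard 95%-asymptotic-efficiency values:
Huber k = 1.345, Tukey biweight k = 4.685.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

HUBER_K = 1.345
TUKEY_K = 4.685


@dataclass(frozen=True)
class Loss:
    name: str
    k: float | None

    def rho(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.name == "l2":
            return 0.5 * t * t
        if self.name == "huber":
            k = self.k
            a = np.abs(t)
            return np.where(a <= k, 0.5 * t * t, k * a - 0.5 * k * k)
        if self.name == "tukey":
            k = self.k
            u = np.clip(t / k, -1.0, 1.0)
            return (k * k / 6.0) * (1.0 - (1.0 - u * u) ** 3)
        raise ValueError(f"unknown loss {self.name!r}")

    def psi(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.name == "l2":
            return t
        if self.name == "huber":
            return np.clip(t, -self.k, self.k)
        if self.name == "tukey":
            u = t / self.k
            inside = np.abs(u) <= 1.0
            return np.where(inside, t * (1.0 - u * u) ** 2, 0.0)
        raise ValueError(f"unknown loss {self.name!r}")

    @property
    def delta(self) -> float:
        """E[psi(Z) Z] under Z ~ N(0,1)."""
        return _delta(self.name, self.k)

    @property
    def rho_max(self) -> float:
        """Supremum of rho (inf for non-redescending losses)."""
        if self.name == "tukey":
            return self.k * self.k / 6.0
        return np.inf


@lru_cache(maxsize=None)
def _delta(name: str, k: float | None) -> float:
    if name == "l2":
        return 1.0
    if name == "huber":
        # E[Z^2; |Z|<=k] + k E[|Z|; |Z|>k] collapses to 2*Phi(k) - 1
        return 2.0 * stats.norm.cdf(k) - 1.0
    if name == "tukey":
        loss = Loss("tukey", k)
        val, _ = integrate.quad(
            lambda z: loss.psi(z) * z * stats.norm.pdf(z), -k, k, limit=200
        )
        return float(val)
    raise ValueError(name)


_LOSSES = {
    "l2": Loss("l2", None),
    "huber": Loss("huber", HUBER_K),
    "tukey": Loss("tukey", TUKEY_K),
}


def get_loss(loss: str | Loss, k: float | None = None) -> Loss:
    """Resolve a loss by name ('l2', 'huber', 'tukey'); `k` overrides the tuning constant."""
    if isinstance(loss, Loss):
        return loss
    try:
        base = _LOSSES[loss]
    except KeyError:
        raise ValueError(f"unknown loss {loss!r}; choose from {sorted(_LOSSES)}") from None
    if k is not None:
        return Loss(base.name, k)
    return base
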