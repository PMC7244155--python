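"""Comparison estimators: sequential discounting EM and the EMA tracker.

SDEM runs one E step and one discounted M step per observation on a
K-component Gaussian mixture; the discount rate ``beta`` geometrically
down-weights old sufficient statistics, and the mixing weights are
epsilon-smoothed with ``gamma_smooth``.  With a single component SDEM
collapses to the exponential moving average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SDEMConfig",
    "SDEMState",
    "EMAState",
    "sdem_responsibilities",
    "sdem_step",
    "ema_step",
]

_LN2PI = math.log(2.0 * math.pi)
LOG_DENSITY_FLOOR = math.log(1e-300)
VARIANCE_FLOOR = 1e-12


@dataclass
class SDEMConfig:
    beta: float
    K: int = 1
    gamma_smooth: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.gamma_smooth <= 0.0:
            raise ValueError("gamma_smooth must be positive")


class SDEMState:
    """Mixture state: raw/smoothed mixing weights and discounted statistics.

    The component parameters satisfy ``mu = mu_tilde / pi_tilde`` and
    ``sigma2 = sigma2_tilde / pi_tilde``; initialisation seeds the tilde
    quantities as ``pi_tilde * value`` so the identity holds from t = 1.
    """

    def __init__(self, config: SDEMConfig, mu0, sigma20, pi0=None, t: int = 1):
        K = config.K
        self.config = config
        self.mu = np.broadcast_to(np.asarray(mu0, dtype=float), (K,)).copy()
        self.sigma2 = np.broadcast_to(np.asarray(sigma20, dtype=float), (K,)).copy()
        if np.any(self.sigma2 <= 0.0):
            raise ValueError("initial variances must be positive")
        self.pi_tilde = (np.full(K, 1.0 / K) if pi0 is None
                         else np.asarray(pi0, dtype=float).copy())
        self.pi = self.pi_tilde / self.pi_tilde.sum()
        self.mu_tilde = self.pi_tilde * self.mu
        self.sigma2_tilde = self.pi_tilde * self.sigma2
        self.q = np.full(K, 1.0 / K)
        self.t = int(t)

    def to_dict(self) -> dict:
        return {
            "config": {"beta": self.config.beta, "K": self.config.K,
                       "gamma_smooth": self.config.gamma_smooth},
            "pi_tilde": self.pi_tilde.tolist(), "pi": self.pi.tolist(),
            "mu_tilde": self.mu_tilde.tolist(), "sigma2_tilde": self.sigma2_tilde.tolist(),
            "mu": self.mu.tolist(), "sigma2": self.sigma2.tolist(),
            "q": self.q.tolist(), "t": self.t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SDEMState":
        state = cls(SDEMConfig(**d["config"]), d["mu"], d["sigma2"], t=d["t"])
        for name in ("pi_tilde", "pi", "mu_tilde", "sigma2_tilde", "mu", "sigma2", "q"):
            setattr(state, name, np.asarray(d[name], dtype=float))
        return state


def sdem_responsibilities(state: SDEMState, d: float) -> np.ndarray:
    """E step: posterior probability of each component for observation ``d``."""
    log_N = (-0.5 * (_LN2PI + np.log(state.sigma2))
             - (float(d) - state.mu) ** 2 / (2.0 * state.sigma2))
    np.maximum(log_N, LOG_DENSITY_FLOOR, out=log_N)
    w = state.pi * np.exp(log_N - log_N.max())
    total = float(w.sum())
    if total <= 0.0:
        raise ValueError("degenerate input: mixture density is zero")
    return w / total


def sdem_step(state: SDEMState, d: float):
    """One discounted E/M step; returns ``(mu, sigma2)`` of the component with
    the highest responsibility."""
    cfg = state.config
    d = float(d)
    q = sdem_responsibilities(state, d)
    state.q = q
    beta = cfg.beta
    one = 1.0 - beta
    # discounted sufficient statistics; the variance term uses the pre-update mean
    state.pi_tilde = one * state.pi_tilde + beta * q
    state.mu_tilde = one * state.mu_tilde + (beta * q) * d
    state.sigma2_tilde = one * state.sigma2_tilde + (beta * q) * (d - state.mu) ** 2
    state.mu = state.mu_tilde / state.pi_tilde
    state.sigma2 = np.maximum(state.sigma2_tilde / state.pi_tilde, VARIANCE_FLOOR)
    g = cfg.gamma_smooth
    state.pi = (state.pi_tilde + g) / (cfg.K * g + float(state.pi_tilde.sum()))
    state.t += 1
    j = int(np.argmax(q))
    return float(state.mu[j]), float(state.sigma2[j])


@dataclass
class EMAState:
    """Exponential moving average of mean and variance with discount ``beta``."""

    mu_ema: float
    sigma2_ema: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.sigma2_ema < 0.0:
            raise ValueError("sigma2_ema must be nonnegative")

    def to_dict(self) -> dict:
        return {"mu_ema": self.mu_ema, "sigma2_ema": self.sigma2_ema, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "EMAState":
        return cls(**d)


def ema_step(state: EMAState, d: float):
    """Convex-combination update; the variance uses the pre-update mean."""
    d = float(d)
    beta = state.beta
    state.sigma2_ema = (1.0 - beta) * state.sigma2_ema + beta * (d - state.mu_ema) ** 2
    state.mu_ema = (1.0 - beta) * state.mu_ema + beta * d
    return state.mu_ema, state.sigma2_ema
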