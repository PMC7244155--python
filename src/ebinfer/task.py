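"""Non-stationary Gaussian stream generator.

The task emits one observation per step from a normal distribution whose
mean and variance are re-drawn from uniform ranges at the start of every
segment (every ``segment_length`` steps, including t = 0), and held constant
in between.  The defaults — mean ~ U[0, 5], variance ~ U[0, 0.1], segments of
1000 steps, 10000 steps total — define the change-point tracking task the
estimators are evaluated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TaskConfig", "TaskTrace", "generate_task", "save_trace_csv", "load_trace_csv"]


@dataclass
class TaskConfig:
    segment_length: int = 1000
    total_steps: int = 10000
    mean_range: tuple[float, float] = (0.0, 5.0)
    var_range: tuple[float, float] = (0.0, 0.1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.segment_length < 1 or self.total_steps < 1:
            raise ValueError("segment_length and total_steps must be >= 1")
        for name, (lo, hi) in (("mean_range", self.mean_range),
                               ("var_range", self.var_range)):
            if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.var_range[0] < 0.0:
            raise ValueError("var_range lower bound must be >= 0")

    def to_dict(self) -> dict:
        return {"segment_length": self.segment_length, "total_steps": self.total_steps,
                "mean_range": list(self.mean_range), "var_range": list(self.var_range),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        d["mean_range"] = tuple(d["mean_range"])
        d["var_range"] = tuple(d["var_range"])
        return cls(**d)


@dataclass
class TaskTrace:
    """Observations plus the ground-truth parameter trajectories."""

    d: np.ndarray
    mu_correct: np.ndarray
    sigma2_correct: np.ndarray
    config: TaskConfig | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.d)


def generate_task(config: TaskConfig, rng=None) -> TaskTrace:
    """Draw a stream.  At each change point the mean is drawn first, then the
    variance (a fixed variate order, so a seed pins the trace shape); the
    observations of the segment are then drawn from the current normal."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.total_steps
    L = config.segment_length
    d = np.empty(T)
    mu_c = np.empty(T)
    s2_c = np.empty(T)
    (mlo, mhi), (vlo, vhi) = config.mean_range, config.var_range
    for start in range(0, T, L):
        mu = mlo + (mhi - mlo) * rng.random()
        s2 = vlo + (vhi - vlo) * rng.random()
        stop = min(start + L, T)
        mu_c[start:stop] = mu
        s2_c[start:stop] = s2
        d[start:stop] = mu + math.sqrt(s2) * rng.standard_normal(stop - start)
    return TaskTrace(d=d, mu_correct=mu_c, sigma2_correct=s2_c, config=config)


def save_trace_csv(trace: TaskTrace, path) -> None:
    """Write the stream as a three-column CSV (full float precision)."""
    pd.DataFrame({"d": trace.d, "mu_correct": trace.mu_correct,
                  "sigma2_correct": trace.sigma2_correct}).to_csv(
        path, index=False, float_format="%.17g")


def load_trace_csv(path, config: TaskConfig | None = None) -> TaskTrace:
    """Read a stream CSV; ``mu_correct``/``sigma2_correct`` columns are
    optional (NaN-filled when absent, e.g. for user-supplied streams)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "d" not in df.columns:
        raise ValueError("stream CSV must have a 'd' column")
    T = len(df)
    nan = np.full(T, np.nan)
    return TaskTrace(
        d=df["d"].to_numpy(dtype=float),
        mu_correct=df["mu_correct"].to_numpy(dtype=float) if "mu_correct" in df else nan,
        sigma2_correct=(df["sigma2_correct"].to_numpy(dtype=float)
                        if "sigma2_correct" in df else nan.copy()),
        config=config)
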