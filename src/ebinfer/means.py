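"""Generalized weighted power means.

The weighted power mean

    mu(x, y | alpha, m) = [(1 - alpha) x^m + alpha y^m]^(1/m)

interpolates between the two conditional probabilities that enter a causal
strength judgement: ``alpha`` weights the two arguments and ``m`` selects the
kind of mean (m=1 arithmetic, m=-1 harmonic, m->0 the geometric limit
``x^(1-alpha) y^alpha``).  The dual-factor-heuristics index of causal
induction is the ``alpha=0.5, m=0`` case.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["generalized_weighted_mean"]


def _log_gen_mean(log_x: float, log_y: float, alpha: float, p: float) -> float:
    """log of the generalized weighted mean, from the logs of its arguments.

    ``p`` is the mean order; ``p == 0`` is the geometric limit.  Working in
    log space keeps large |p| and extreme argument ratios from overflowing.
    """
    if alpha <= 0.0:
        return log_x
    if alpha >= 1.0:
        return log_y
    if p == 0.0 or abs(p) * (1.0 + (log_x - log_y) ** 2) < 1e-9:
        # geometric limit; also taken for tiny |p| where dividing the
        # log-sum-exp by p would amplify rounding into overflow
        return (1.0 - alpha) * log_x + alpha * log_y
    a = math.log1p(-alpha) + p * log_x
    b = math.log(alpha) + p * log_y
    hi = a if a >= b else b
    return (hi + math.log1p(math.exp(min(a, b) - hi))) / p


def generalized_weighted_mean(x: float, y: float, alpha: float, m: float) -> float:
    """Weighted power mean of two positive numbers.

    Parameters
    ----------
    x, y
        Positive finite values to average.
    alpha
        Weight on ``y``, in [0, 1].  ``alpha=0`` returns ``x`` exactly,
        whatever ``m``.
    m
        Mean order; ``m=0`` denotes the geometric-mean limit
        ``x**(1-alpha) * y**alpha``.

    Returns
    -------
    float
        A value between ``min(x, y)`` and ``max(x, y)``.
    """
    x = float(x)
    y = float(y)
    if not (np.isfinite(x) and np.isfinite(y)) or x <= 0.0 or y <= 0.0:
        raise ValueError(f"arguments must be positive and finite, got x={x}, y={y}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    out = math.exp(_log_gen_mean(math.log(x), math.log(y), alpha, float(m)))
    # betweenness can be violated by a rounding ulp; enforce it exactly
    lo, hi = (x, y) if x <= y else (y, x)
    return min(max(out, lo), hi)
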