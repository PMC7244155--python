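"""Extended Bayesian inference (EBI) for univariate Gaussian streams.

The estimator maintains K hypothesis models, each a normal distribution
``N(mu_k, Sigma_k)``.  Every observation updates the confidence over the
hypotheses with a forgetting exponent ``alpha`` (the prior enters as
``C^(1-alpha)``), and then *learns*: the likelihood of the max-confidence
hypothesis is pulled toward the observation (inverse Bayesian inference) and
the model parameters are recovered in closed form — the mean by inverting the
normal density, the variance by inverting a gamma density over a sliding
window of squared residuals via the two real branches of the Lambert W
function.

At ``alpha = 0`` the learning passes vanish and the confidence recursion is
exactly the standard Bayesian filter; at ``alpha > 0`` old evidence decays
geometrically and the hypothesis models themselves track the stream.

All density arithmetic is done in log space: a collapsed variance drives the
gamma scale ``lambda`` large enough that a naive ``lambda**S`` overflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, lambertw

from .means import _log_gen_mean

__all__ = [
    "EBIConfig",
    "HypothesisModel",
    "EBIState",
    "update_confidences",
    "select_max_hypothesis",
    "ebi_target_likelihood",
    "invert_normal_mean",
    "push_residual",
    "invert_gamma_scale",
    "ebi_step",
]

#: densities are floored here before entering ratios, preventing 0/0
LOG_DENSITY_FLOOR = math.log(1e-300)
#: hard floor on any variance produced by the gamma inversion
VARIANCE_FLOOR = 1e-12
_BRANCH_POINT = -1.0 / math.e
_LN2PI = math.log(2.0 * math.pi)


class NumericalInversionError(RuntimeError):
    """Raised when a closed-form density inversion produces a non-finite value."""


@dataclass
class EBIConfig:
    """Parameters of the EBI estimator.

    alpha : forgetting/learning rate in [0, 1] (0 = plain Bayes).
    m : order of the generalized mean coupling the two conditional
        probabilities; 0 is the geometric-mean limit used in the main
        experiments, negative orders emphasise the smaller argument.
    K : number of hypotheses.
    epsilon : smoothing and clipping floor (default 1e-10).
    n : residual-window length for the variance model; the windowed sum of
        squared residuals follows a gamma distribution with shape S = n/2.
    learning_alpha : optional separate learning rate for the likelihood
        update; ``None`` means the single ``alpha`` plays both roles.
    delta_variance : which variance enters the density normalizer of the
        mean pass — "post" (after this step's variance update, the default)
        or "pre".
    """

    alpha: float
    m: float = 0.0
    K: int = 1
    epsilon: float = 1e-10
    n: int = 20
    learning_alpha: float | None = None
    delta_variance: str = "post"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.learning_alpha is not None and not 0.0 <= self.learning_alpha <= 1.0:
            raise ValueError("learning_alpha must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError("residual window length n must be an even integer >= 2")
        if self.delta_variance not in ("pre", "post"):
            raise ValueError("delta_variance must be 'pre' or 'post'")

    @property
    def S(self) -> float:
        """Gamma shape parameter, exactly n/2."""
        return self.n / 2.0

    @property
    def effective_learning_alpha(self) -> float:
        return self.alpha if self.learning_alpha is None else self.learning_alpha

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "m": self.m,
            "K": self.K,
            "epsilon": self.epsilon,
            "n": self.n,
            "learning_alpha": self.learning_alpha,
            "delta_variance": self.delta_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EBIConfig":
        return cls(**d)


@dataclass
class HypothesisModel:
    """One hypothesis: a normal model plus its gamma-scale bookkeeping.

    ``lam`` is the gamma-model scale, tied to the normal variance by
    ``lam = 1 / (2 * sigma2)``.  ``residuals`` is the window of squared
    deviations recorded while this hypothesis was max-confident, oldest
    first; ``n_k`` counts how often it has been max-confident.
    """

    mu: float
    sigma2: float
    lam: float | None = None
    residuals: list[float] = field(default_factory=list)
    n_k: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0.0:
            raise ValueError("sigma2 must be positive")
        if self.lam is None:
            self.lam = 1.0 / (2.0 * self.sigma2)
        elif abs(self.lam * 2.0 * self.sigma2 - 1.0) > 1e-12:
            raise ValueError("lam must equal 1/(2*sigma2)")


def push_residual(hyp: HypothesisModel, d: float, n: int):
    """Record ``(d - mu)**2`` in the hypothesis's circular residual window.

    Returns the windowed sum ``D`` once the window holds exactly ``n``
    entries, ``None`` during warm-up.  The squared deviation uses the
    hypothesis's *current* mean (the model that predicted ``d``).
    """
    r = (float(d) - hyp.mu) ** 2
    if len(hyp.residuals) == n:
        hyp.residuals.pop(0)
    hyp.residuals.append(r)
    hyp.n_k += 1
    if len(hyp.residuals) == n:
        return sum(hyp.residuals)
    return None


class EBIState:
    """Full estimator state: K hypothesis models plus the confidence vector.

    Internally the models are stored as flat arrays for speed; the
    :attr:`hypotheses` property materialises :class:`HypothesisModel` views.
    """

    def __init__(self, config: EBIConfig, hypotheses, confidence=None, t: int = 1,
                 max_index: int | None = None):
        if len(hypotheses) != config.K:
            raise ValueError(f"expected {config.K} hypotheses, got {len(hypotheses)}")
        self.config = config
        n = config.n
        K = config.K
        self.mu = np.array([h.mu for h in hypotheses], dtype=float)
        self.sigma2 = np.array([h.sigma2 for h in hypotheses], dtype=float)
        self.lam = np.array([h.lam for h in hypotheses], dtype=float)
        self.n_k = np.array([h.n_k for h in hypotheses], dtype=np.int64)
        self._win = np.zeros((K, n), dtype=float)
        self._win_sum = np.zeros(K, dtype=float)
        for k, h in enumerate(hypotheses):
            res = list(h.residuals)
            if len(res) != min(h.n_k, n):
                raise ValueError("residual window length must equal min(n_k, n)")
            self._store_window(k, res, h.n_k)
        if confidence is None:
            self.conf = np.full(K, 1.0 / K)
        else:
            self.conf = np.asarray(confidence, dtype=float).copy()
            if self.conf.shape != (K,) or np.any(self.conf <= 0.0):
                raise ValueError("confidence must be K positive entries")
            if abs(self.conf.sum() - 1.0) > 1e-9:
                raise ValueError("confidence must sum to 1")
        self.t = int(t)
        self.max_index = max_index
        self._gammaln_S = float(gammaln(config.S))

    @classmethod
    def initialize(cls, config: EBIConfig, mu0=2.5, sigma20=0.05) -> "EBIState":
        """Fresh state with uniform confidence 1/K over identical or given models."""
        mu0 = np.broadcast_to(np.asarray(mu0, dtype=float), (config.K,))
        sigma20 = np.broadcast_to(np.asarray(sigma20, dtype=float), (config.K,))
        models = [HypothesisModel(mu=float(m), sigma2=float(s))
                  for m, s in zip(mu0, sigma20)]
        return cls(config, models)

    # -- residual window ---------------------------------------------------

    def _store_window(self, k: int, residuals_time_order, n_k: int,
                      window_sum: float | None = None) -> None:
        n = self.config.n
        res = np.asarray(residuals_time_order, dtype=float)
        if n_k <= n:
            self._win[k, :len(res)] = res
        else:
            pos = n_k % n
            self._win[k, pos:] = res[: n - pos]
            self._win[k, :pos] = res[n - pos:]
        self.n_k[k] = n_k
        self._win_sum[k] = float(res.sum()) if window_sum is None else window_sum

    def _residuals_time_order(self, k: int) -> list[float]:
        n = self.config.n
        nk = int(self.n_k[k])
        if nk <= n:
            return [float(v) for v in self._win[k, :nk]]
        pos = nk % n
        return [float(v) for v in self._win[k, pos:]] + [float(v) for v in self._win[k, :pos]]

    def _push(self, k: int, r: float):
        """O(1) circular push; returns the window sum once the window is full."""
        n = self.config.n
        nk = int(self.n_k[k])
        pos = nk % n
        if nk >= n:
            self._win_sum[k] += r - self._win[k, pos]
        else:
            self._win_sum[k] += r
        self._win[k, pos] = r
        self.n_k[k] = nk + 1
        if nk + 1 >= n:
            return float(self._win_sum[k])
        return None

    # -- views and serialization ------------------------------------------

    @property
    def hypotheses(self) -> list[HypothesisModel]:
        return [
            HypothesisModel(mu=float(self.mu[k]), sigma2=float(self.sigma2[k]),
                            lam=float(self.lam[k]),
                            residuals=self._residuals_time_order(k),
                            n_k=int(self.n_k[k]))
            for k in range(self.config.K)
        ]

    @property
    def confidence(self) -> np.ndarray:
        return self.conf.copy()

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "hypotheses": [
                {"mu": float(self.mu[k]), "sigma2": float(self.sigma2[k]),
                 "lam": float(self.lam[k]), "n_k": int(self.n_k[k]),
                 "residuals": self._residuals_time_order(k),
                 "window_sum": float(self._win_sum[k])}
                for k in range(self.config.K)
            ],
            "confidence": [float(c) for c in self.conf],
            "t": self.t,
            "max_index": self.max_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EBIState":
        config = EBIConfig.from_dict(d["config"])
        models = [HypothesisModel(mu=h["mu"], sigma2=h["sigma2"], lam=h["lam"],
                                  residuals=list(h["residuals"]), n_k=h["n_k"])
                  for h in d["hypotheses"]]
        state = cls(config, models, confidence=d["confidence"], t=d["t"],
                    max_index=d.get("max_index"))
        for k, h in enumerate(d["hypotheses"]):
            if "window_sum" in h:
                state._win_sum[k] = float(h["window_sum"])
        return state


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _logsumexp(v: np.ndarray) -> float:
    m = float(v.max())
    if not math.isfinite(m):
        return m
    return m + math.log(float(np.exp(v - m).sum()))


def _log_normal_pdf(d: float, mu: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    out = -0.5 * (_LN2PI + np.log(sigma2)) - (d - mu) ** 2 / (2.0 * sigma2)
    return np.maximum(out, LOG_DENSITY_FLOOR, out=out)


def update_confidences(state: EBIState, d: float) -> np.ndarray:
    """One confidence update with forgetting and epsilon-smoothing.

    The unnormalized score of hypothesis k divides the joint
    ``C_k * F(d | theta_k)`` by the generalized mean (order ``-m``) of the
    probability-ized data evidence ``Delta * G`` and the prior ``C_k``; at
    ``m = 0`` common factors cancel and the score reduces to
    ``C_k**(1 - alpha) * F(d | theta_k)``.  The returned vector is
    ``(s_k + eps) / (K * eps + sum_j s_j)``.
    """
    cfg = state.config
    d = float(d)
    log_F = _log_normal_pdf(d, state.mu, state.sigma2)
    log_C = np.log(state.conf)
    a = cfg.alpha
    if a == 0.0:
        log_s = log_C + log_F
    elif a >= 1.0:
        log_s = log_F.copy()
    elif cfg.m == 0.0:
        log_s = (1.0 - a) * log_C + log_F
    else:
        # general m: the data-evidence term no longer cancels; probability-ize
        # the density mixture with Delta from the current max-confidence model
        j = int(np.argmax(state.conf))
        log_delta = 0.5 * (_LN2PI + math.log(float(state.sigma2[j])))
        log_dg = log_delta + _logsumexp(log_C + log_F)
        p = -cfg.m
        A = math.log1p(-a) + p * log_dg
        B = math.log(a) + p * log_C
        hi = np.maximum(A, B)
        log_div = (hi + np.log1p(np.exp(np.minimum(A, B) - hi))) / p
        # rescale by the common (Delta*G)^(1-alpha) so the score scale seen by
        # the epsilon-smoothing matches the m=0 form continuously
        log_s = log_C + log_F - log_div + (1.0 - a) * log_dg
    s = np.exp(np.clip(log_s, -745.0, 700.0))
    eps = cfg.epsilon
    return (s + eps) / (cfg.K * eps + float(s.sum()))


def select_max_hypothesis(confidence, rng=None) -> int:
    """Index of the max-confidence hypothesis; exact ties broken uniformly at
    random via ``rng`` (first index if no rng is given)."""
    conf = np.asarray(confidence, dtype=float)
    if conf.size == 0:
        raise ValueError("confidence vector is empty")
    j = int(np.argmax(conf))
    ties = np.flatnonzero(conf == conf[j])
    if ties.size > 1 and rng is not None:
        j = int(ties[rng.integers(ties.size)])
    return j


def _log_target_likelihood(log_c_max: float, log_mixture: float, log_density: float,
                           alpha: float, log_delta: float, m: float) -> float:
    if alpha <= 0.0:
        return log_density
    return log_c_max + log_density - _log_gen_mean(
        log_c_max, log_delta + log_mixture, alpha, -m)


def ebi_target_likelihood(C_max: float, mixture: float, current_density: float,
                          alpha: float, Delta: float, m: float = 0.0) -> float:
    """Post-update likelihood of the max-confidence hypothesis.

    At ``m = 0`` this is ``(1/Delta**alpha) * (C_max/mixture)**alpha * f``
    with ``f`` the current density; general ``m`` replaces the geometric
    coupling by the order ``-m`` generalized mean of ``C_max`` and
    ``Delta * mixture``.
    """
    if not (C_max > 0.0 and current_density > 0.0 and Delta > 0.0):
        raise ValueError("C_max, current_density and Delta must be positive")
    if mixture <= 0.0:
        raise ValueError("degenerate update: mixture density is zero")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return math.exp(_log_target_likelihood(
        math.log(C_max), math.log(mixture), math.log(current_density),
        alpha, math.log(Delta), m))


def _invert_normal_log(d: float, log_target: float, sigma2_new: float,
                       mu_old: float, epsilon: float):
    log_peak = -0.5 * (_LN2PI + math.log(sigma2_new))
    lt = min(max(log_target, math.log(epsilon)), log_peak)
    # lt - log_peak = log(clipped * sqrt(2 pi sigma2)) <= 0; a target within
    # an ulp of the peak snaps to it so the zero-offset root is exact
    diff = lt - log_peak
    if diff > -1e-15:
        return d, log_peak
    off = math.sqrt(-2.0 * sigma2_new * diff)
    mu1 = d - off
    mu2 = d + off
    # root nearer the old mean keeps the accumulated history; tie -> smaller
    mu_new = mu1 if abs(mu1 - mu_old) <= abs(mu2 - mu_old) else mu2
    return mu_new, lt


def invert_normal_mean(d: float, target_likelihood: float, sigma2_new: float,
                       mu_old: float, epsilon: float = 1e-10):
    """Solve ``N(d | mu_new, sigma2_new) = target`` for the mean.

    The target is first clipped into ``[epsilon, peak]`` with
    ``peak = 1/sqrt(2 pi sigma2_new)``; of the two symmetric roots
    ``d +/- offset`` the one closer to ``mu_old`` is returned (the smaller on
    a tie).  Returns ``(mu_new, clipped_likelihood)``.
    """
    if sigma2_new <= 0.0:
        raise ValueError("sigma2_new must be positive")
    if target_likelihood <= 0.0:
        raise ValueError("target_likelihood must be positive")
    mu_new, lt = _invert_normal_log(float(d), math.log(target_likelihood),
                                    float(sigma2_new), float(mu_old), epsilon)
    return mu_new, math.exp(lt)


def _invert_gamma_log(D: float, log_target: float, S: float, lambda_old: float,
                      epsilon: float, gammaln_S: float):
    log_absZ = (math.log(D) + log_target + gammaln_S) / S - math.log(S)
    if not math.isfinite(log_absZ):
        raise NumericalInversionError(
            f"non-finite Z in gamma inversion (D={D}, log_target={log_target})")
    Z = -math.exp(log_absZ)
    Z = max(min(Z, -epsilon), _BRANCH_POINT)
    if Z <= _BRANCH_POINT:
        # branch point W(-1/e) = -1; lambertw NaNs on the rounded float
        theta = -1.0
    else:
        theta1 = float(lambertw(Z, -1).real)
        theta2 = float(lambertw(Z, 0).real)
        theta_ref = -lambda_old * D / S
        theta = theta1 if abs(theta1 - theta_ref) <= abs(theta2 - theta_ref) else theta2
    lam = -S * theta / D
    sigma2 = 1.0 / (2.0 * lam)
    if sigma2 < VARIANCE_FLOOR:
        sigma2 = VARIANCE_FLOOR
        lam = 1.0 / (2.0 * sigma2)
    return lam, sigma2


def invert_gamma_scale(D: float, target_likelihood: float, S: float,
                       lambda_old: float, epsilon: float = 1e-10):
    """Solve ``Gamma(D | shape=S, scale=lambda) = target`` for the scale.

    The transformed target ``Z = -(D * target * Gamma(S))**(1/S) / S`` is
    clipped into ``[-1/e, -epsilon]``; both real Lambert W branches solve
    ``Z = Theta * exp(Theta)`` and the branch value nearer the Theta implied
    by ``lambda_old`` is kept.  Returns ``(lambda_new, sigma2_new)`` with
    ``sigma2_new = 1/(2*lambda_new)``.
    """
    if D <= 0.0 or S <= 0.0 or lambda_old <= 0.0:
        raise ValueError("D, S and lambda_old must be positive")
    if target_likelihood <= 0.0:
        raise ValueError("target_likelihood must be positive")
    return _invert_gamma_log(float(D), math.log(target_likelihood), float(S),
                             float(lambda_old), epsilon, float(gammaln(S)))


def ebi_step(state: EBIState, d: float, rng=None):
    """Advance the estimator by one observation.

    Order of operations: confidence update -> max-confidence selection ->
    residual push (pre-update mean) -> gamma/variance learning (only once the
    residual window is full) -> normal/mean learning -> time increment.
    Only the selected hypothesis's model changes.  Returns the post-update
    ``(mu, sigma2)`` of the selected hypothesis.
    """
    cfg = state.config
    d = float(d)
    if not math.isfinite(d):
        raise ValueError(f"observation must be finite, got {d}")
    conf = update_confidences(state, d)
    state.conf = conf
    j = select_max_hypothesis(conf, rng)
    state.max_index = j

    a = cfg.effective_learning_alpha
    mu_old = float(state.mu[j])
    sig_old = float(state.sigma2[j])
    D = state._push(j, (d - mu_old) ** 2)

    if a > 0.0:
        log_C = np.log(conf)
        S = cfg.S
        if D is not None and D > 0.0:
            # variance pass: gamma model over the windowed squared residuals
            logD = math.log(D)
            glS = state._gammaln_S
            log_f = S * np.log(state.lam) + (S - 1.0) * logD - state.lam * D - glS
            np.maximum(log_f, LOG_DENSITY_FLOOR, out=log_f)
            log_G = _logsumexp(log_C + log_f)
            log_delta = glS + logD + S - S * math.log(S)
            log_t = _log_target_likelihood(float(log_C[j]), log_G, float(log_f[j]),
                                           a, log_delta, cfg.m)
            lam_new, sig_new = _invert_gamma_log(D, log_t, S, float(state.lam[j]),
                                                 cfg.epsilon, glS)
            state.lam[j] = lam_new
            state.sigma2[j] = sig_new
        # mean pass: normal model, Delta from the (by default) updated variance
        sig_pass = sig_old if cfg.delta_variance == "pre" else float(state.sigma2[j])
        sig_vec = state.sigma2.copy()
        sig_vec[j] = sig_pass
        log_N = _log_normal_pdf(d, state.mu, sig_vec)
        log_G = _logsumexp(log_C + log_N)
        log_delta = 0.5 * (_LN2PI + math.log(sig_pass))
        log_t = _log_target_likelihood(float(log_C[j]), log_G, float(log_N[j]),
                                       a, log_delta, cfg.m)
        mu_new, _ = _invert_normal_log(d, log_t, float(state.sigma2[j]), mu_old,
                                       cfg.epsilon)
        state.mu[j] = mu_new

    state.t += 1
    return float(state.mu[j]), float(state.sigma2[j])
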