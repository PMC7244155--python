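"""Core estimator operations: confidence updating, selection, inversions,
and the full per-observation step against an independent scalar oracle."""

import json
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import lambertw

from ebinfer import (EBIConfig, EBIState, HypothesisModel, ebi_step,
                     ebi_target_likelihood, invert_gamma_scale,
                     invert_normal_mean, push_residual,
                     select_max_hypothesis, update_confidences)

EPS = 1e-10


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        EBIConfig(alpha=1.5)
    with pytest.raises(ValueError):
        EBIConfig(alpha=0.1, K=0)
    with pytest.raises(ValueError):
        EBIConfig(alpha=0.1, n=7)  # window length must be even
    with pytest.raises(ValueError):
        EBIConfig(alpha=0.1, epsilon=0.0)
    assert EBIConfig(alpha=0.1, n=20).S == 10.0
    assert EBIConfig(alpha=0.1, n=6).S == 3.0


def test_hypothesis_model_ties_lambda_to_variance():
    h = HypothesisModel(mu=0.0, sigma2=0.05)
    assert h.lam == pytest.approx(10.0, rel=1e-12)
    with pytest.raises(ValueError):
        HypothesisModel(mu=0.0, sigma2=0.05, lam=3.0)
    with pytest.raises(ValueError):
        HypothesisModel(mu=0.0, sigma2=-1.0)


def test_state_initialize_uniform_confidence():
    st = EBIState.initialize(EBIConfig(alpha=0.1, K=4), 2.5, 0.05)
    assert np.allclose(st.conf, 0.25)
    assert st.t == 1
    assert all(h.n_k == 0 and h.residuals == [] for h in st.hypotheses)


# ---------------------------------------------------------------------------
# confidence update
# ---------------------------------------------------------------------------

def test_update_confidences_alpha_zero_is_bayes(two_hypothesis_state):
    st = two_hypothesis_state
    st.config.alpha = 0.0
    d = 1.3
    dens = stats.norm.pdf(d, st.mu, np.sqrt(st.sigma2))
    s = st.conf * dens
    expected = (s + EPS) / (2 * EPS + s.sum())
    out = update_confidences(st, d)
    assert np.allclose(out, expected, rtol=1e-12, atol=0)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_update_confidences_alpha_one_discards_prior():
    # identical models, lopsided prior: with full forgetting the posterior
    # depends only on the (equal) current likelihoods
    cfg = EBIConfig(alpha=1.0, K=2)
    st = EBIState(cfg, [HypothesisModel(2.0, 0.05), HypothesisModel(2.0, 0.05)],
                  confidence=[0.9, 0.1])
    out = update_confidences(st, 2.7)
    assert np.allclose(out, [0.5, 0.5], atol=1e-12)


def test_update_confidences_smoothing_floor():
    # one model is hopeless for the datum; its confidence stays positive
    cfg = EBIConfig(alpha=0.2, K=2)
    st = EBIState(cfg, [HypothesisModel(0.0, 0.01), HypothesisModel(50.0, 0.01)])
    out = update_confidences(st, 0.0)
    assert 0.0 < out[1] < 1e-9  # epsilon floor, not exactly zero
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_update_confidences_general_m_reduces_to_geometric_at_zero(two_hypothesis_state):
    st = two_hypothesis_state
    st.config.alpha = 0.3
    d = 2.0
    st.config.m = 0.0
    ref = update_confidences(st, d)
    st.config.m = 1e-9
    near = update_confidences(st, d)
    assert np.allclose(near, ref, atol=1e-6)


# ---------------------------------------------------------------------------
# max-confidence selection
# ---------------------------------------------------------------------------

def test_select_max_unique_and_singleton(rng):
    assert select_max_hypothesis([0.2, 0.7, 0.1], rng) == 1
    assert select_max_hypothesis([1.0], rng) == 0
    with pytest.raises(ValueError):
        select_max_hypothesis([], rng)


def test_select_max_tie_is_uniform(rng):
    draws = np.array([select_max_hypothesis([0.5, 0.5], rng) for _ in range(2000)])
    counts = np.bincount(draws, minlength=2)
    assert stats.chisquare(counts).pvalue > 1e-3


# ---------------------------------------------------------------------------
# likelihood target and inversions
# ---------------------------------------------------------------------------

def test_target_likelihood_alpha_zero_identity():
    assert ebi_target_likelihood(0.3, 0.2, 0.7, 0.0, 5.0) == pytest.approx(0.7, rel=1e-14)


def test_target_likelihood_matches_closed_form():
    C, G, f, a, D = 0.6, 0.25, 0.8, 0.35, 2.1
    expected = (1 / D ** a) * (C / G) ** a * f
    assert ebi_target_likelihood(C, G, f, a, D) == pytest.approx(expected, rel=1e-12)


def test_target_likelihood_fixed_point_iteration():
    # K=1: the mixture is the single hypothesis's own density, so the map
    # x <- (1/Delta)^a x^(1-a) climbs monotonically to 1/Delta
    x = 0.1
    prev = x
    for _ in range(200):
        x = ebi_target_likelihood(1.0, x, x, 0.5, 1.0)
        assert x >= prev - 1e-15
        prev = x
    assert x == pytest.approx(1.0, abs=1e-10)


def test_invert_normal_mean_peak_and_clipping():
    s2 = 0.05
    peak = 1 / math.sqrt(2 * math.pi * s2)
    mu, clipped = invert_normal_mean(1.0, peak, s2, mu_old=0.3)
    assert mu == 1.0 and clipped == pytest.approx(peak)
    mu, clipped = invert_normal_mean(1.0, 10 * peak, s2, mu_old=0.3)
    assert mu == 1.0 and clipped == pytest.approx(peak)


def test_invert_normal_mean_half_peak_left_root():
    s2 = 0.05
    peak = 1 / math.sqrt(2 * math.pi * s2)
    mu, clipped = invert_normal_mean(1.0, peak / 2, s2, mu_old=0.8)
    assert mu == pytest.approx(1 - math.sqrt(0.1 * math.log(2)), rel=1e-12)
    assert stats.norm.pdf(1.0, mu, math.sqrt(s2)) == pytest.approx(clipped, rel=1e-10)


def test_invert_normal_mean_tie_takes_smaller_root():
    s2 = 0.05
    peak = 1 / math.sqrt(2 * math.pi * s2)
    mu, _ = invert_normal_mean(1.0, peak / 2, s2, mu_old=1.0)
    assert mu < 1.0


def test_push_residual_window_lifecycle():
    h = HypothesisModel(mu=0.0, sigma2=0.05)
    assert push_residual(h, 0.5, n=20) is None  # warm-up
    assert len(h.residuals) == 1 and h.n_k == 1
    for _ in range(18):
        assert push_residual(h, 0.5, n=20) is None
    D = push_residual(h, 0.5, n=20)
    assert D == pytest.approx(5.0, rel=1e-12)  # 20 x 0.25
    D = push_residual(h, 1.0, n=20)  # evicts the oldest 0.25
    assert len(h.residuals) == 20 and h.n_k == 21
    assert D == pytest.approx(19 * 0.25 + 1.0, rel=1e-12)


def test_invert_gamma_scale_branch_point_clip():
    # an overlarge target drives Z below -1/e; after clipping W(-1/e) = -1
    # and the recovered scale puts the gamma mean at D
    lam, s2 = invert_gamma_scale(2.0, 1e6, 10.0, lambda_old=5.0)
    assert lam == pytest.approx(5.0, rel=1e-12)
    assert s2 == pytest.approx(0.1, rel=1e-12)


def test_invert_gamma_scale_roundtrip_known_scale():
    target = stats.gamma.pdf(2.0, a=10, scale=1 / 5.0)
    lam, s2 = invert_gamma_scale(2.0, target, 10.0, lambda_old=5.0)
    assert lam == pytest.approx(5.0, rel=1e-8)
    assert s2 == pytest.approx(1 / (2 * lam), rel=1e-12)


def test_invert_gamma_scale_both_branches(rng):
    # Theta < -1 exercises W_-1, Theta in (-1, 0) exercises W_0
    for theta_true in (-3.0, -1.7, -0.6, -0.1):
        D = rng.uniform(0.5, 4.0)
        S = 10.0
        lam_true = -S * theta_true / D
        target = stats.gamma.pdf(D, a=S, scale=1 / lam_true)
        lam, _ = invert_gamma_scale(D, target, S, lambda_old=lam_true * 1.001)
        assert lam == pytest.approx(lam_true, rel=1e-8)


def test_invert_gamma_rejects_bad_inputs():
    with pytest.raises(ValueError):
        invert_gamma_scale(-1.0, 0.5, 10.0, 1.0)
    with pytest.raises(ValueError):
        invert_gamma_scale(1.0, 0.0, 10.0, 1.0)


# ---------------------------------------------------------------------------
# full step vs an independent scalar oracle
# ---------------------------------------------------------------------------

def _oracle_step(conf, mus, s2s, lams, window_sums, window_full, d, alpha,
                 eps=1e-10, S=10.0):
    """Direct transcription of the update chain using scipy densities.

    ``window_sums``/``window_full`` describe the residual window *after* this
    step's push for the selected hypothesis (the caller mirrors the push).
    """
    K = len(conf)
    dens = stats.norm.pdf(d, mus, np.sqrt(s2s))
    s = conf ** (1 - alpha) * dens
    C = (s + eps) / (K * eps + s.sum())
    j = int(np.argmax(C))
    r = (d - mus[j]) ** 2
    mus = mus.copy()
    s2s = s2s.copy()
    lams = lams.copy()
    if window_full[j]:
        D = window_sums[j]
        f = stats.gamma.pdf(D, a=S, scale=1 / lams)
        G = float((C * f).sum())
        Delta = math.gamma(S) * D * math.exp(S) / S ** S
        tgt = (1 / Delta ** alpha) * (C[j] / G) ** alpha * f[j]
        Z = -(D * tgt * math.gamma(S)) ** (1 / S) / S
        Z = max(min(Z, -eps), -1 / math.e)
        if Z <= -1 / math.e:
            th = -1.0
        else:
            th1 = float(lambertw(Z, -1).real)
            th2 = float(lambertw(Z, 0).real)
            ref = -lams[j] * D / S
            th = th1 if abs(th1 - ref) <= abs(th2 - ref) else th2
        lams[j] = -S * th / D
        s2s[j] = 1 / (2 * lams[j])
    dens2 = stats.norm.pdf(d, mus, np.sqrt(s2s))
    G = float((C * dens2).sum())
    Delta = math.sqrt(2 * math.pi * s2s[j])
    tgt = (1 / Delta ** alpha) * (C[j] / G) ** alpha * dens2[j]
    peak = 1 / math.sqrt(2 * math.pi * s2s[j])
    tgt = min(max(tgt, eps), peak)
    off = math.sqrt(max(-2 * s2s[j] * math.log(tgt * math.sqrt(2 * math.pi * s2s[j])), 0))
    mu1, mu2 = d - off, d + off
    mus[j] = mu1 if abs(mu1 - mus[j]) <= abs(mu2 - mus[j]) else mu2
    return C, j, r, mus, s2s, lams


def test_ebi_step_matches_oracle_warmup():
    # residual windows not yet full: only the mean is learned
    cfg = EBIConfig(alpha=0.15, m=0.0, K=2)
    st = EBIState(cfg, [HypothesisModel(1.0, 0.05), HypothesisModel(4.0, 0.08)],
                  confidence=[0.35, 0.65])
    d = 3.4
    C, j, _, mus, s2s, _ = _oracle_step(
        st.conf.copy(), st.mu.copy(), st.sigma2.copy(), st.lam.copy(),
        np.zeros(2), [False, False], d, 0.15)
    ebi_step(st, d)
    assert st.max_index == j
    assert np.allclose(st.conf, C, rtol=1e-12, atol=1e-15)
    assert np.allclose(st.mu, mus, rtol=1e-12, atol=1e-12)
    assert np.allclose(st.sigma2, s2s, rtol=1e-12, atol=0)


def test_ebi_step_matches_oracle_with_gamma_pass(rng):
    # pre-filled windows so the variance is learned through the gamma model
    cfg = EBIConfig(alpha=0.2, m=0.0, K=2, n=20)
    res_a = list(rng.uniform(0.01, 0.2, 20))
    res_b = list(rng.uniform(0.01, 0.2, 20))
    st = EBIState(cfg, [
        HypothesisModel(1.0, 0.05, residuals=res_a, n_k=20),
        HypothesisModel(4.0, 0.08, residuals=res_b, n_k=20)],
        confidence=[0.3, 0.7])
    d = 3.9
    # mirror the push for the hypothesis the step will select
    dens = stats.norm.pdf(d, st.mu, np.sqrt(st.sigma2))
    s = st.conf ** 0.8 * dens
    C = (s + EPS) / (2 * EPS + s.sum())
    j = int(np.argmax(C))
    res = [res_a, res_b][j]
    new_sum = sum(res[1:]) + (d - st.mu[j]) ** 2
    sums = np.array([sum(res_a), sum(res_b)])
    sums[j] = new_sum
    Co, jo, _, mus, s2s, lams = _oracle_step(
        st.conf.copy(), st.mu.copy(), st.sigma2.copy(), st.lam.copy(),
        sums, [True, True], d, 0.2)
    assert jo == j
    ebi_step(st, d)
    assert np.allclose(st.conf, Co, rtol=1e-12, atol=1e-15)
    assert np.allclose(st.mu, mus, rtol=1e-12, atol=1e-12)
    assert np.allclose(st.sigma2, s2s, rtol=1e-10, atol=0)
    assert np.allclose(st.lam, lams, rtol=1e-10, atol=0)


def test_ebi_step_only_selected_hypothesis_changes(rng):
    cfg = EBIConfig(alpha=0.3, m=0.0, K=4)
    st = EBIState.initialize(cfg, rng.uniform(0, 5, 4), rng.uniform(0.02, 0.1, 4))
    for _ in range(300):
        mu_before = st.mu.copy()
        s2_before = st.sigma2.copy()
        nk_before = st.n_k.copy()
        d = rng.normal(2.5, 1.0)
        ebi_step(st, d, rng)
        j = st.max_index
        others = [k for k in range(4) if k != j]
        assert np.array_equal(st.mu[others], mu_before[others])
        assert np.array_equal(st.sigma2[others], s2_before[others])
        assert np.array_equal(st.n_k[others], nk_before[others])
        assert st.n_k[j] == nk_before[j] + 1


def test_confidence_conservation_and_floor(rng):
    cfg = EBIConfig(alpha=0.25, m=0.0, K=5)
    st = EBIState.initialize(cfg, rng.uniform(0, 5, 5), rng.uniform(0.02, 0.1, 5))
    for _ in range(500):
        ebi_step(st, rng.normal(2.0, 1.5), rng)
        assert st.conf.sum() == pytest.approx(1.0, abs=1e-9)
        # the epsilon smoothing keeps every confidence strictly positive
        assert np.all(st.conf > 0.0)
        assert np.all(st.conf < 1.0)
        assert np.allclose(st.lam * 2.0 * st.sigma2, 1.0, rtol=1e-12)


def test_alpha_zero_never_learns(rng):
    cfg = EBIConfig(alpha=0.0, m=0.0, K=3)
    mu0 = np.array([1.0, 2.5, 4.0])
    st = EBIState.initialize(cfg, mu0, 0.05)
    for _ in range(200):
        ebi_step(st, rng.normal(2.5, 0.3), rng)
    assert np.array_equal(st.mu, mu0)
    assert np.all(st.sigma2 == 0.05)


def test_state_json_checkpoint_resume(rng):
    cfg = EBIConfig(alpha=0.1, m=0.0, K=2, n=6)
    stream = rng.normal(2.0, 0.5, 120)
    full = EBIState.initialize(cfg, [1.0, 3.0], 0.05)
    for d in stream:
        ebi_step(full, d)
    half = EBIState.initialize(cfg, [1.0, 3.0], 0.05)
    for d in stream[:60]:
        ebi_step(half, d)
    resumed = EBIState.from_dict(json.loads(json.dumps(half.to_dict())))
    for d in stream[60:]:
        ebi_step(resumed, d)
    assert np.array_equal(resumed.mu, full.mu)
    assert np.array_equal(resumed.sigma2, full.sigma2)
    assert np.array_equal(resumed.conf, full.conf)
    assert np.array_equal(resumed._win, full._win)
    assert resumed.t == full.t


def test_ebi_step_rejects_nonfinite_observation(two_hypothesis_state):
    with pytest.raises(ValueError):
        ebi_step(two_hypothesis_state, math.nan)
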