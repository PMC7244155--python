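# ebinfer — extended Bayesian inference for non-stationary streams

`ebinfer` is an online estimator for univariate Gaussian data streams whose
generating distribution changes abruptly — the setting of change-point
tracking, anomaly detection warm-up, or modelling an observer who must infer
a hidden state (an emotion, a regime, a source) that drifts while being
estimated. It implements **extended Bayesian inference (EBI)**: Bayesian
updating in which the conditional-probability weighting is replaced by a
generalized weighted mean of the two conditional probabilities linking
hypothesis and data, which simultaneously introduces *forgetting* of old
evidence and *inverse-Bayesian learning* of the hypothesis models
themselves. The two reference baselines — sequential discounting EM (SDEM)
for Gaussian mixtures and the exponential moving average (EMA) — ship
alongside, with the stream generator and evaluation protocol used to compare
them.

## The model

The estimator keeps `K` hypotheses, each a normal model `N(μ_k, Σ_k)`, and a
confidence vector `C(h_k)`. The causal-strength index is the generalized
weighted mean

    μ(x, y | α, m) = [(1−α) x^m + α y^m]^(1/m),      μ(x, y | α, 0) = x^(1−α) y^α,

applied to `P(d|h)` and `P(h|d)`. Folding this into the Bayesian recursion
gives, at the geometric limit `m = 0`,

* **forgetting** — confidences update as `C^(t+1)(h_k) ∝ C(h_k)^(1−α) F(d|θ_k)`,
  so evidence `i` steps old is weighted `(1−α)^i` (with an ε-smoothing floor
  keeping every confidence positive), and
* **learning** — the likelihood of the max-confidence hypothesis is moved to
  `C^(t+1)(d|h_max) = (1/Δ^α) [C(h_max)/C(d)]^α F(d|θ_max)` and the model
  parameters are recovered in closed form: the mean by inverting the normal
  density (the root nearer the old mean), the variance by inverting a gamma
  density with shape `S = n/2` over a sliding window of `n = 20` squared
  residuals, via the two real branches of the Lambert W function. `Δ` is the
  reciprocal peak density of the current model, so repeated observations of
  the same value drive the model density toward its vertex.

`α = 0` reduces exactly to standard Bayesian filtering (no forgetting, no
learning); `α = 0.5, m = 0` is the dual-factor-heuristics index of human
causal induction. General `m` interpolates the kind of mean (arithmetic at
`m=1`, harmonic at `m=−1`); negative or zero orders track markedly better
than positive ones.

Performance is measured on a stream whose mean (`~ U[0,5]`) and variance
(`~ U[0,0.1]`) are re-drawn every 1000 steps: the RMSE of the first half of
each segment is the **followability error** (lag after a change), the second
half the **accuracy error** (noise during stationarity). For the EMA these
two are a strict trade-off in the discount rate β; the hypothesis-switching
estimator bends that frontier.

## Worked example

```bash
python examples/01_track_nonstationary_stream.py
```

```
method            : EBI  (alpha=0.018, m=0, K=10)
followability RMSE: 0.1958   (mean error over the first half of each 1000-step segment)
accuracy RMSE     : 0.0281   (mean error over the second half, once the estimate has settled)
total RMSE        : 0.1750   (whole stream)
```

For contrast, `examples/02_compare_methods.py` runs all three estimators at
the same discount rate 0.03 (three trials, random initial models):

```
method   K  followability   accuracy    total
EBI     10         0.0756     0.0174   0.0682
SDEM    10         0.1219     0.0321   0.1103
EMA      1         0.2849     0.0241   0.2405
```

The EMA must pick a point on its trade-off curve; the EBI's learned
hypothesis bank reacts faster *and* sits quieter. The other examples show
the discount sweep and the lossless CSV export/replay path.

The same experiments are available from the shell:

```bash
ebinfer simulate --method ebi --alpha 0.018 --m 0 --K 10 --seed 1 --out runs/demo
ebinfer sweep --trials 10 --seed-base 0 --out runs/sweep
ebinfer replay --input stream.csv --method sdem --beta 0.03 --K 10
```

Every run writes a `manifest.json` from which it can be reproduced
bit-identically (`ebinfer.cli.run_from_manifest`).

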