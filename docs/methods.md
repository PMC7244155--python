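# Methods

## Estimation problem

A univariate stream `d^1, d^2, …` is generated by a normal distribution
whose mean and variance change abruptly at unknown times. The estimator
must report, online and without lookahead, a running estimate `(μ̂^t, Σ̂^t)`
of the current generating parameters. The difficulty is the classic
discounting dilemma: a short memory follows changes quickly but is noisy in
the stationary stretches, a long memory is accurate but lags.

## Extended Bayesian inference

### Confidence update (forgetting)

Each of `K` hypotheses carries a normal model `F(d|θ_k) = N(d; μ_k, Σ_k)`
and a confidence `C(h_k)`. Replacing the likelihood weighting of Bayes'
rule by the generalized weighted mean `μ(x,y|α,m) = [(1−α)x^m + αy^m]^{1/m}`
of `P(d|h)` and `P(h|d)` yields, after expressing everything through the
joint, the unnormalized score

    s_k = C(h_k) · F(d|θ_k) / μ(ΔG, C(h_k) | α, −m) · (ΔG)^{1−α},

where `G = Σ_j C(h_j) F(d|θ_j)` is the density mixture and `Δ` converts the
density `G` to a probability-like quantity (see below). At the geometric
limit `m = 0` the data-evidence term is a common factor and the score
reduces to the familiar exponential-forgetting form

    s_k = C(h_k)^{1−α} · F(d|θ_k),

which is the form used in all headline experiments; the trailing
`(ΔG)^{1−α}` rescaling in the general case exists only to keep the absolute
score scale continuous in `m` (the smoothing below is scale-sensitive).
The new confidences are smoothed and normalized in one step,

    C(h_k) ← (s_k + ε) / (Kε + Σ_j s_j),      ε = 10⁻¹⁰,

so no confidence ever reaches exactly zero. Note the guaranteed floor is
`ε/(Kε + Σ_j s_j)`; because densities can exceed 1 there is no useful
constant lower bound, only strict positivity. With `α = 0` the recursion is
exactly the standard Bayesian filter for every `m`, a reduction the tests
check against an independently coded filter.

### Likelihood learning (inverse Bayesian inference)

Only the max-confidence hypothesis `h_max` (ties broken uniformly at random
from a dedicated RNG) learns. Its likelihood target is

    C^{t+1}(·|h_max) = C(h_max) · F / μ(C(h_max), ΔG | α, −m)
                     = (1/Δ^α) [C(h_max)/G]^α F        (at m = 0),

a geometric step of size `α` from the current density `F` toward the
probability-ized posterior ratio. `Δ` is chosen as the reciprocal of the
model's peak density, which makes the `K=1` recursion a contraction with
fixed point at the density vertex: on a constant stream the model converges
onto the datum (verified to `|μ−c| < 10⁻³` after 500 steps at `α = 0.1`).

Two closed-form inversions then map the target back to parameters:

* **Mean.** `N(d|μ', Σ') = target` has the two roots
  `μ' = d ± sqrt(−2Σ' log(target·sqrt(2πΣ')))`. The target is first clipped
  into `[ε, 1/sqrt(2πΣ')]` so a root always exists; the root nearer the old
  mean is kept (preserving accumulated history), the smaller on the exact
  tie `μ_old = d` (where both give the same density). A target within an
  ulp of the peak snaps to the zero-offset root `μ' = d` exactly.
* **Variance.** The windowed sum `D` of the last `n = 20` squared residuals
  of `h_max` (recorded with the pre-update mean, i.e. the model that
  predicted the datum) is gamma-distributed with shape `S = n/2` and scale
  `λ = 1/(2Σ)`; its mean is `nΣ`. Solving `Gamma(D|λ', S) = target` reduces
  to `Z = Θ e^Θ` with `Θ = −λ'D/S` and
  `Z = −(D·target·Γ(S))^{1/S}/S`, clipped into `[−1/e, −ε]`. Both real
  Lambert W branches are candidate solutions; the branch value nearer the
  `Θ` implied by the current scale (`Θ_ref = −λ_old D/S`) is kept, mirroring
  the nearest-root rule of the mean case. Until a hypothesis's window has
  collected `n` residuals the variance update is skipped entirely rather
  than fabricating unobserved residuals; `λ = 1/(2Σ)` is maintained as an
  exact invariant, with the initial `λ` implied by the initial variance.

Per observation the order is: confidence update → selection → residual push
→ variance learning (gamma pass, with its own `Δ = Γ(S)·D·e^S/S^S`, the
reciprocal gamma density whose mean sits at `D`) → mean learning (normal
pass) → time increment. The reported estimate is the post-update `(μ, Σ)`
of the selected hypothesis; all other hypotheses' models are bit-identical
before and after the step.

### Variance timing in the mean pass

The density normalizer of the mean pass is `Δ = sqrt(2πΣ_max)`. Whether
`Σ_max` is the pre- or post-variance-update value is genuinely open; the
default (`delta_variance="post"`) uses the just-updated variance
consistently for `Δ`, the mixture's `h_max` component, the clip bound and
the inversion, which keeps the fixed-point argument self-consistent. The
alternative (`"pre"`) is a config switch. For the general-`m` confidence
update, `Δ` is taken from the *pre-update* max-confidence hypothesis, since
`h_max` is only selected after that update; at `m = 0` the choice cancels
and has no effect.

## Baselines

**SDEM** runs one E step (responsibilities `q_k ∝ π_k N(d|μ_k, Σ_k)`) and
one discounted M step per observation: sufficient statistics decay at rate
`1−β`, `π̃ ← (1−β)π̃ + βq`, `μ̃ ← (1−β)μ̃ + βqd`,
`Σ̃ ← (1−β)Σ̃ + βq(d−μ)²` (pre-update mean), with parameters recovered as
ratios and mixing weights smoothed by `γ = 0.001`. The reported component
is the one with the highest responsibility. With `K = 1` the mean recursion
is algebraically the EMA; the implementation preserves this to better than
10⁻¹² over 10⁴ steps. **EMA** applies the convex-combination update
directly, the variance using the pre-update mean.

## Task generator

The default task re-draws the mean from `U[0, 5]` and the variance from
`U[0, 0.1]` at `t = 0` and every 1000 steps thereafter (10000 steps total),
holding them constant in between; observations are normal draws from the
current parameters. At a change point the mean variate is consumed before
the variance variate, fixing a seed's trace shape. Streams round-trip
losslessly through CSV (`%.17g`, round-trip float parsing).

What the generator does *not* emulate: drifting (non-piecewise-constant)
regimes, heavy-tailed or skewed emission noise, correlated observations,
and change points that are unaligned with a fixed grid. Passing tests
therefore certify behaviour under abrupt, independent, Gaussian regime
changes only; real sensor or behavioural streams can violate each of these.

## Evaluation protocol

Each 1000-step segment is halved: the RMSE of the first half is the
followability error, of the second half the accuracy error; per-segment
values are averaged across segments (not pooled), then across trials. The
discount sweep covers 48 rates (0.009 to 0.15, step 0.003); the `(α, m)`
grid covers `α ∈ [0.05, 0.5]` (step 0.05) × `m ∈ [−2, 2]` (step 0.1). Two
initialization policies exist: fixed (`μ = 2.5, Σ = 0.05`, used for
single-trace demonstrations) and per-trial uniform (`μ ~ U[0,5]`,
`Σ ~ U[0,0.1]`, used for sweeps — applied to all three methods, including
the EMA, for fairness). Trials differ only in seeds; each trial derives
three independent generators from its seed (data, tie-breaking,
initialization) via fixed offsets, so estimator randomness is decoupled
from the stream.

## Parameters that matter

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | forgetting and learning rate, `[0,1]` | — | 0 = plain Bayes; the sweep range 0.009–0.15 brackets useful values; a single `α` plays both roles (a separate `learning_alpha` is available) |
| `m` | generalized-mean order | 0 | `m ≤ 0` performs well, `m > 0` degrades tracking; 0 is the geometric limit |
| `K` | hypotheses / components | 1 | performance grows with `K` for the EBI; 10 used in the comparisons |
| `epsilon` | smoothing/clipping floor | 1e-10 | also the `Z` clip bound in the gamma inversion |
| `n` | residual window | 20 | gamma shape `S = n/2 = 10`; even, ≥ 2 |
| `beta` | baseline discount rate | — | `(0,1)`; same sweep grid |
| `gamma_smooth` | SDEM weight smoothing | 0.001 | |

## Numerical choices

All density arithmetic is in log space (densities floored at 10⁻³⁰⁰ before
entering ratios): after the variance collapses toward its 10⁻¹² floor the
gamma scale `λ` is large enough that `λ^S` overflows in linear arithmetic.
`Z` at the Lambert branch point is special-cased to `Θ = −1` because the
nearest double to `−1/e` lies outside the function's domain. Exact
confidence ties (which occur when all models are identical, e.g. at the
first step under fixed initialization) are broken uniformly at random —
this is also what breaks the symmetry of an initially identical hypothesis
bank. Degenerate windowed sums (`D ≤ 0`, possible only on an exactly
constant stream) skip the variance update.

## Problem sizes

The shipped checks use 10 trials for the discount sweep, 20 for the
mean-order contrast and 100 streams of length 1000 for the exact-reduction
check; the acceptance script uses 10/5/3 trials for the comparison, grid
and sweep respectively. These sizes give stable orderings (the qualitative
results above are decisive at 3–10 trials) while keeping a full run in the
minutes range on one core.

## Known limitations

One-dimensional observations only; likelihoods of non-max hypotheses are
never updated (by design); no model selection over `K`; the `(α, m)` fit to
human causal-judgement data is out of scope. The variance estimate inherits
a window-length lag of `n` steps after a change, and transiently large
variances are possible when the `W₀` branch is selected near `Z → 0`.
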