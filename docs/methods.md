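# Methods

## The model family

The package models a trial-by-trial motor-timing experiment.  On trial *n* an
agent produces a duration *t_p* aimed at a hidden target *t_t*; the relative
error is *e_n = (t_p − t_t)/t_t* and binary feedback *r_n* marks whether
|*e_n*| fell inside a symmetric acceptance window.  Human series in this task
show two signatures: serial correlation of *e* extending over roughly twenty
trials (memory drift around the target), and variability on the next trial
that is larger after negative feedback than after positive feedback.

The central model, the weight-varying autoregressive network (vARNN), is an
order-*p* autoregression whose weights are multiplicatively noised on every
trial, with the noise variance gated by the feedback each lagged trial
received:

    w_i(r) ~ w_i · Normal(1, σ₋²(1−r) + σ₊²r)
    e_n    = h( Σ_i w_i(r_{n−i}) e_{n−i} + b ) + ε_n,     ε_n ~ Normal(0, σ₀²)

with *h(x) = max(x, −1)*.  The autoregressive backbone carries the long-range
correlation; the reward-gated weight noise carries the short-term variability
adjustment (σ₋² > σ₊² means noise shrinks after success).  Setting
σ₊² = σ₋² = 0 yields the ARNN: deterministic weights, additive output noise
only.  A GRU with inputs [e_{n−1}, r_{n−1}] (hidden size 32, linear readout)
serves as the generic sequence-model baseline.

Two modelling choices deserve note.  First, the activation is implemented as
the shifted hinge max(x, −1) — rectification of (x+1) followed by shifting
back — because the rectifier's purpose is to guarantee e > −1 (equivalently
t_p > 0), and errors in this task straddle zero; a plain rectification of
(x+1) would forbid negative errors outright.  Second, the additive noise ε_n
is applied after the activation, following the generative equation; in
extreme parameter regimes a draw can therefore land marginally below −1, and
such regimes are treated as unphysical (the session container rejects them).

The one-step predictive distribution has closed form in the linear regime:

    mean      = h( Σ_i w_i e_{n−i} + b )
    variance  = Σ_i w_i² e_{n−i}² [σ₋²(1−r_{n−i}) + σ₊²r_{n−i}] + σ₀²

The hinge is ignored for the variance; at the operating scale (|e| ≲ 0.3) it
is essentially never active, and the test suite bounds the approximation
error against 10⁵-draw Monte-Carlo simulation at 5% over random
configurations.

## Task simulator

`task_sim` closes the loop: a target is drawn once per session from
Normal(800 ms, 80 ms) (redrawn if non-positive), the model emits *e_n*,
*t_p = t_t(1 + e_n)*, and feedback is issued by a symmetric window on |e|.
The window rule is a running median of |e| over the previous 100 trials
(fixed half-width 0.1 for the first 50 trials): the median is the minimal
rule whose fixed point is a 50% reward rate, which is how the human task was
calibrated.  The window boundary is inclusive.  One master seed per session
drives every draw through numpy `SeedSequence` spawning, so sessions are
bit-reproducible.

What the simulator does *not* emulate: attentional lapses, session-length
non-stationarity (fatigue, learning trends), effector differences between eye
and hand movements, and any latency structure within a trial.  Passing tests
on this synthetic data therefore demonstrate correctness of the algorithms
and recoverability of the model's own structure, not goodness-of-fit to real
human behavior.

### Reference parameter sets

Defaults were chosen once to emulate the published behavioral regime and are
not tuned per analysis:

* `default_varnn_params`: p = 20, geometrically decaying weights summing to
  0.8 (PACF profile decaying over ~20 trials, like the human series),
  σ₀ = 0.06 (overall error SD ≈ 0.1), σ₊² = 0.1, σ₋² = 0.44 — the ratio
  σ₊²/σ₋² = 0.227 matches the reported human median of 0.226.
* `low_order_varnn_params`: p = 1, w = 0.5, same noise variances with
  σ₀² = 0.01 — used where the reward-gated variance signature or model
  comparison is itself the object of study, because a dominant lag-1 weight
  makes the signature analysable.
* `pacf_demo_arnn_params`: p = 20, all weights 0.04, σ₀ = 0.1, no weight
  noise — the series whose PACF run extends to exactly lag 20.
* `recovery_grid`: p ∈ {1, 3, 5}, weights in [0.05, 0.6], σ₊² = 0.1,
  σ₋²/σ₊² ∈ {1, 2, 4}, σ₀² = 0.01.  Larger weight-noise bases push the
  generator out of the physical regime (emissions at or below e = −1), which
  bounds how strong the simulated gating can be made.

## Training

The residual objective is the inverse-variance weighted MSE
Res = (1/N) Σ g_n (ê_n − e_n)² with g_n = 1/σ_n² (Aitken weighting; plain MSE
under uniform weights), plus the penalty

    P = λ₁ (1/p) Σ_i [ 2/(1 + e^(−c₁|w_i|^(1/c₂))) − 1 ]  +  λ₂ [σ₋²/σ₊² + σ₊²/σ₋²]

with c₁ = c₂ = 3 and λ₁ = λ₂ = 0.01·Var(e) by default.  The first term is a
smooth sparsity surrogate (steep near zero, saturating at one per weight)
that lets the fit start from a generous order (p = 20, or the PACF run length
of the data) and shrink surplus lags; the second keeps the two weight-noise
variances in a sane ratio.

Each epoch alternates two updates on the 80% training split (random split
without replacement, per session; the first p trials of each session are
excluded as burn-in):

1. **Mean step** (w, b): one full-batch gradient step on the weighted
   residual with the trial weights frozen at the epoch's start
   (iteratively-reweighted scheme) and the weight noise reparameterized as
   w_i(1 + √σ²(r) ξ), ξ ~ Normal(0,1), drawn fresh per trial per epoch, so
   the gradient flows through the deterministic path.  Plain SGD with
   momentum 0.9, learning rate 10⁻², 500-epoch cap.  Because this gradient
   is stochastic, the reported mean parameters are a trailing (Polyak-style)
   average of the iterates.
2. **Noise-variance step** (σ₊², σ₋², σ₀²): the bare weighted residual is
   *not* a valid objective for the variances — shrinking predicted variances
   only ever reduces a frozen-weight squared error, and inflating them
   reduces the reweighted one — so variance updates maximize the Gaussian
   likelihood, whose log σ_n² normalizer makes them identifiable.  During
   training a damped iteratively-reweighted regression of squared residuals
   on the variance design supplies weights for step 1; the reported variances
   come from a final penalized maximum-likelihood refinement (L-BFGS in log
   space, multi-start) at the selected mean parameters.

Epoch and restart selection use the penalized Gaussian negative
log-likelihood on the validation split (for the same identifiability
reason).  Early stopping follows the validation-above-training rule with
patience 10, guarded so the streak only counts epochs that fail to improve
the best validation loss — the unguarded rule fires spuriously whenever the
fixed validation split happens to be slightly harder than the training
split.  Ten random restarts by default; the best-validation restart is
reported.  ARNN fits pin both weight-noise variances at zero (uniform
weights; σ₀² is the mean squared residual).  GRU fits are teacher-forced
one-step training on segments of 100 trials with 50% overlap (each target
counted once), hidden state reset per segment, masked MSE with L1 10⁻⁴ on
the gate weights, SGD with momentum.

The randomly-weighted residual (rwMSE) — the self-normalized residual under
uniform-random trial weights — is the null for informed weighting: 1,000
redraws of the weights on fixed forecasts give a null distribution against
which the informed (1/σ_n²) residual is compared.

### Identifiability of the reward-gated variances

A structural point that shapes what parameter recovery can show: with a
performance-calibrated window, rewarded trials are by construction the
small-|e| trials, so the after-success variance σ₊² multiplies only small
regressors (w_i² e² ≤ w_i² × the window width squared).  Its per-fit Fisher
standard error at 10 sessions × 1,000 trials is ≈ 0.3 — three times the
reference value 0.1 — and this cannot be engineered away: the rewarded-trial
e² is capped near 0.2 Var(e) by the median window, and the output-noise share
of total variance cannot fall below roughly half for a stationary
multiplicative-noise process.  σ₋² is well identified (it multiplies the
large-error trials).  Consequently individual fitted variance *ratios* are
noisy around an attenuated trend, and the recovery suite tests the ratio as a
rank correlation across the fit grid plus a directional check at the largest
contrast, not as a strict ordering of three noisy medians.  Weight recovery
is unaffected (grid correlation > 0.95, per-coefficient error ≲ 0.05).

## Behavioral analyses

* **PACF with shuffle bands**: partial autocorrelation by lagged-regressor
  least squares (regression of e_n on its first k lags with intercept, per-lag
  row alignment identical to running each regression separately), computed
  efficiently from one Gram matrix with exact per-lag corrections; a
  Durbin–Levinson recursion on the sample autocorrelation is the
  cross-check.  The confidence band is the pooled 1%/99% quantile pair of
  PACF values over trial shuffles (default 1,000), which destroy serial
  structure while preserving the marginal distribution.  For an AR(p)
  process the PACF cuts off after lag p, so the consecutive significant run
  estimates the memory span; `infer_order` uses it to set the fit order.
* **Reward-conditioned statistics**: mean, variance and reward fraction of
  e_n in equal-count bins of e_{n−1}, split by r_{n−1} (bins under 50
  transitions merged; transitions never span session boundaries).  The
  formal variance-asymmetry test partials the mean dependence on e_{n−1} out
  by regression and compares residual variances of the two feedback groups
  with a one-sided F-test — binned controls leak here, because the
  near-constant window splits boundary bins into disjoint |e| ranges by r.
* **Residual ratio**: self-normalized weighted unexplained variance divided
  by total variance (a weighted 1 − R²); 1 means structureless, 0 fully
  predictable.  vARNN fits are scored with their own predictive variances as
  weights; ARNN and GRU, having constant predictive variance, are scored
  uniformly.
* **Running mean**: centered 20-trial moving average, shrinking at edges.

## Problem sizes and numerical choices

Analyses in the test suite use the reference scale of the simulation studies:
10 sessions × 1,000 trials per parameter set, 10⁵-draw Monte-Carlo for the
variance oracle, 20,000-trial series for PACF studies, 1,000 shuffle/null
replicates.  Multi-restart counts are reduced from 10 to 2–3 in the scripted
studies; on this synthetic family restarts agree closely and the reduction
does not change any conclusion.  Paired model comparisons use one-sided sign
tests across sessions at α = 0.05 with no multiplicity correction (three
planned comparisons).  Variances are optimized in log space with physical
caps (weight-noise variance ≤ 2; a relative weight perturbation beyond that
scale puts the generator outside e > −1).  Degenerate inputs raise: empty
sessions, non-binary rewards, non-positive targets, non-finite model
emissions (with the offending trial named), zero predictive variance in
weighting.

## Known limitations

* Gradients are hand-derived (no autodiff); the GRU backward pass and the
  reparameterized gradients are finite-difference-checked in the tests.
* The closed-form predictive variance ignores the hinge; far outside the
  operating regime (means near −1) it overstates the true variance.
* The GRU baseline is a single layer with a linear readout and plain
  momentum SGD; it is a fair but not exhaustively tuned competitor.
* Per-session fitted variance ratios are noisy (see identifiability above);
  population-level statements (medians, rank correlations) are the supported
  use.
* The simulator's stationary window calibration makes the long-run reward
  rate 0.5 by construction; tasks with drifting difficulty are out of scope.
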