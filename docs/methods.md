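# Methods

## Model

`pwlds` implements recurrent switching linear dynamical systems (rSLDS) of
the "recurrent only" kind, and their single-mode special case, the linear
dynamical system (LDS).  A discrete mode `z_t ∈ {1..K}` selects one of K
linear laws for the continuous latent state `x_t ∈ R^H`:

    z_{t+1} | x_t   ~  π_SB(R x_t + r)
    x_{t+1}         =  A_{z_{t+1}} x_t + b_{z_{t+1}} + v_t,    v_t ~ N(0, Q_{z_{t+1}})

`π_SB` is the stick-breaking link: logits `ν ∈ R^{K-1}` are split
sequentially, position j keeping a fraction `σ(ν_j)` of the remaining stick
and the last position receiving the residual.  A single `(R, r)` is shared
by all modes, so the mode partition is a fixed set of regions of latent
space — the piecewise-linear structure.  Observations are either
linear-Gaussian, `y_t = C x_t + d + w_t` with `w_t ~ N(0, S)`, or Poisson
spike counts with a softplus rate, `y_t ~ Poisson(softplus(C x_t + d))`.
With K = 1 the transition parameters vanish and the model is a plain LDS;
`reduce_to_lds` exposes that view, and all results through it are identical
by construction.

A mode with spectral radius of `A` below one is asymptotically stable and
has the point attractor `x* = (I − A)^{-1} b`.

### Mode ordering and hard boundaries

The stick order is a stored permutation mapping stick positions to mode
indices.  Fitted models use the identity order; the ground-truth simulator
uses the order (Mode 2, Mode 3, Mode 1) because a band-shaped region
(`|x_1 − x_2| ≤ threshold`) can only be the *residual* of two linear sticks.
Ground-truth models are marked `hard`: simulation assigns the next mode by
argmax of the transition probabilities, so the mode sequence is a
deterministic function of the continuous trajectory (hard region
boundaries).  A tiny (1e-9) logit offset keeps states exactly on the
boundary inside the accumulation band, making the band closed.

## Synthetic decision dynamics

The generator emulates two-alternative perceptual decision making as a
three-mode system in a 2-D latent space:

| parameter | default | meaning |
|---|---|---|
| attractors | (1, 6), (6, 1) | commitment targets of choices 1 and 2 |
| switch threshold | 1 latent unit | band half-width on `x_1 − x_2` |
| start state | (0, 0) | every trial starts at the origin |
| `mode1_drift` | 0.2 / bin | diagonal drift of the accumulation mode |
| `mode_contraction` | 0.9 | `A = 0.9 I` in the attractor modes |
| `process_noise_var` | 0.04 | accumulation-mode isotropic noise |
| `attractor_noise_var` | 1e-3 | attractor-mode isotropic noise |
| `trial_length` | 50 bins | |

Attractor locations, the threshold, and the origin start are the reference
configuration of the simulated task; drift, noise, and trial length are not
dictated by it and were chosen once so that the difference coordinate
`x_1 − x_2` (a random walk with per-bin variance `2 × 0.04`) first crosses
the threshold around bin 12–16 — mid-trial on the 50-bin horizon — and so
that ≈95% of trials commit before the trial ends.  Trials that never leave
the accumulation mode keep an unset choice label, are flagged, and are
excluded from choice decoding.  Whether the process noise differs across
modes is a free choice; the attractor modes get small noise so committed
trajectories hug their attractor.

Gaussian emissions use random rows of `C` with expected unit norm, `d = 0`,
and `S = σ² I` (reference: 5 dimensions, σ² = 0.01).  Poisson emissions are
calibrated: per-neuron target mean rates are drawn from a log-normal across
neurons whose 10th/90th percentiles match the configured spread (defaults
0.1 and 5 spikes/bin at a grand mean of 2), sampled by stratified quantiles
so the sample percentiles sit on target, and rescaled to hit the grand mean
exactly; each neuron receives a random latent direction scaled to unit drive
standard deviation, and its offset `d_n` is solved by bisection so the
time-averaged `softplus(c_n·x + d_n)` over simulated trajectories equals the
neuron's target.  The calibration contract is a grand-mean rate within 5%
of target.

What the generator does *not* emulate: refractoriness or spike-history
effects, non-Poisson dispersion, slow nonstationarities, unequal sensory
evidence (the drift asymmetry is exposed as configuration but defaults to
symmetric), and reaction-time-dependent trial lengths.  Passing tests on
these data therefore demonstrate correct recovery of piecewise-linear
structure under the model's own assumptions, not robustness to the many ways
real recordings violate them.

## Inference

Fitting is variational EM with a structured mean field `q(z) q(x)` per
trial:

* **q(x)** is a joint Gaussian over the trajectory with block-tridiagonal
  precision.  Given mode responsibilities, the expected dynamics terms are
  quadratic, and the posterior follows from one information-form smoothing
  pass (a batched block-tridiagonal solve).
* **q(z_t)** are independent categoricals.  Because the recurrent-only
  transition depends only on `x_t`, the optimal `q(z)` factorizes over time
  exactly — no forward–backward recursion over z exists to be approximated.
* The stick-breaking terms `log σ(±ν)` are handled with the Jaakkola–Jordan
  quadratic bound with per-stick variational parameters ξ (closed-form
  update `ξ² = E[ν²]`, capped at 100 for numerical range).  The objective is
  therefore a proper evidence lower bound, and for the Gaussian family every
  update — q(x), q(z), ξ, and all M-steps — increases it, which is what the
  "ELBO trace non-decreasing" contract tests.  The reported ELBO equals the
  exact log marginal likelihood for K = 1 Gaussian models (verified against
  a Kalman-filter oracle at 1e-6).
* **Poisson emissions** use a Laplace update for q(x): damped Newton on the
  MAP trajectory (the per-cell log-likelihood `y log softplus(η) −
  softplus(η)` is concave in η), with the Gaussian approximation taken at
  the optimum.  The emission term of the bound uses a second-order expansion
  around the posterior mean.  Ascent is therefore approximate for Poisson;
  strict monotonicity is only asserted for the Gaussian family.

**Damping.**  Mode responsibilities otherwise harden within one or two
sweeps and pin the continuous state to one region.  Both q(z) and the q(x)
mean are therefore updated by the convex combination
`(1 − lr)·old + lr·proposed` (default lr = 0.25, configurable); the q(x)
covariance is recomputed from the proposed precision.  Because the proposed
values are exact coordinate maximizers of a concave objective, damped steps
still ascend the bound.

**Update order.**  Each sweep updates ξ, then q(z), then q(x).  Updating
q(z) first matters at initialization: the initial continuous-state means
carry the data-driven starting point, and a q(x) update under the
uninformative uniform q(z) would average the K mode dynamics and collapse
that structure before the modes ever see it.  (With Gaussian low-noise
observations the emissions re-anchor q(x) and the order is immaterial; with
Poisson observations the per-bin likelihood is weak and the order decides
which basin EM lands in.)

**M-steps** are closed-form weighted least squares for `(A_k, b_k, Q_k)`
(eigenvalue floor 1e-8 on covariances), for `(C, d)` and diagonal `S`
(Gaussian), and for `(R, r)` under the ξ-bound, with a trust region limiting
each row's step (the unconstrained maximizer overshoots wildly once
boundaries saturate and the bound's curvature vanishes; a truncated step
toward the maximizer of a concave quadratic still ascends).  Poisson
`(C, d)` use per-neuron backtracked Newton on the emission likelihood at the
posterior means — a generalized M-step.  The initial state `(μ0, Σ0, π0)` is
re-estimated by moment matching with a probability floor of 1e-6.

**Initialization** (per restart, seeded): PCA of the observations (for
counts: standardized by `sqrt(mean + 0.25)`, temporally smoothed with a
5-bin boxcar before clustering — per-bin spike counts are too noisy for
k-means to see the region structure); global least-squares dynamics;
k-means clustering of the latent scores into K modes with per-cluster
dynamics; a stick-breaking logistic fit of the cluster labels for `(R, r)`;
and jitter on `A_k` and `R`.  The mode responsibilities are seeded from the
cluster labels at 0.85 confidence (an uninformative uniform start loses the
race against the damped q(x) collapse described above).  `infer_posterior`
under a *fixed* model keeps the uniform q(z) start, as its contract states.

**Numerical floors:** logits clipped at ±30 in the stick-breaking link;
covariance eigenvalue floor 1e-8; ξ capped at 100; Newton line searches
halve up to 12–15 times.

## Forecasting

Forecasts are causal.  A per-trial assumed-density filter (exact Kalman
filter for K = 1 Gaussian) propagates a single Gaussian belief plus mode
probabilities: per-mode predict, per-mode measurement update (Kalman or
single-site Laplace), reweighting by the measurement likelihoods, and
moment-matched collapse.  From the filtered state at origin t, k-step
predictions are Monte-Carlo rollouts (default 100 seeded samples; latent
start drawn from the filtered Gaussian, modes sampled from the
stick-breaking probabilities, process noise added); the observation forecast
is `C x̄ + d` for Gaussian data and the sample mean of the softplus rate for
counts.  A deterministic most-likely-mode rollout is available
(`method="mode"`).  The Monte-Carlo default was chosen because mode
switching makes the exact predictive mean intractable; sampling is unbiased
and reproducible under a seed.

Evaluation uses every origin `t` with `t + k` inside the trial, aggregating
per trial into the multi-dimensional R² and MED per horizon (per-trial
distributions feed the paired Wilcoxon tests; pooled curves are obtained by
averaging).  Latent-space evaluation compares rollout means against the
simulator's true latents and is only meaningful after aligning the model to
ground-truth coordinates.

## Metrics

* `med` — mean over time of the Euclidean residual norm.
* `r2_euclidean` — `1 − Σ‖y_t − ŷ_t‖² / Σ‖y_t − ȳ‖²` with the time-mean
  null predictor; exactly 0 for the mean predictor, 1 for a perfect one.
* `poisson_deviance` — `y log(y/μ) − (y − μ)` with `0·log 0 = 0`.  The
  conventional factor of 2 is deliberately absent, matching the definition
  used for the ratio; it would cancel in the R² anyway.
* `r2_deviance_poisson` — deviance ratio against the per-neuron mean-count
  null; all-zero neurons are excluded with a warning.
* `expected_r2_poisson` — the numerator deviances replaced by
  `E_{y~Poisson(μ)}[D(y, μ)]`, computed by a truncated series up to
  `μ + 10√μ + 20` (tail error < 1e-12 for μ ≤ 100); the denominator keeps
  the observed counts.  `E[D] → 1/2` as μ → ∞ and ≈ 0.573 at μ = 1.

## Alignment and discrepancy

A fitted model is identified only up to an affine change of latent
coordinates `x̂ = F x + g`.  The transform is solved from the two emission
maps (`Ĉ F = C`, `Ĉ g = d − d̂`) by pseudo-inverse (exact when `Ĉ` is
square/invertible, least squares with a recorded residual otherwise), and
all parameters are mapped back: `A' = F⁻¹ Â F`, `b' = F⁻¹(Â g + b̂ − g)`,
`R' = R̂ F`, `r' = R̂ g + r̂`, `C' = Ĉ F`, `d' = Ĉ g + d̂`, covariances
congruently.  Round trips recover constructed instances to 1e-8.

The discrepancy between an aligned model and the truth sums three
components: the mean distance between matched attractor fixed points; the
fraction of a state-space grid ([−1, 8]², step 0.05) with differing mode
assignments, scaled by 2.0; and the mean absolute difference of sorted
eigenvalue moduli of matched modes.  Modes are matched by a linear
assignment on fixed-point distances, falling back to region overlap for
modes without fixed points (the accumulation mode has `A = I`).  Totals are
thresholded into excellent (< 0.5), good (0.5–2, closed) and poor (> 2).
The exact weighting of the published score is not documented anywhere we
could find; the components, the grid, the scale of 2.0 on the boundary term
(full disagreement alone reaches the "poor" boundary) and the unweighted sum
are this package's choices, exposed as configuration.  Classification
thresholds and qualitative ordering are robust to that choice; absolute
third-decimal agreement with any particular published score value is not
claimed.

## Choice embedding and decoding

The difference-response matrix `D = 0.5 (x̄_choice1 − x̄_choice2)` (rows =
time steps, trials truncated to the common length) is the per-bin
half-difference of choice-conditioned trial-averaged latents.  A PCA on its
rows (centered by default, toggleable) gives the 2-D projection that
preserves choice separation.  Decoding trains a linear-kernel SVM (C = 1,
unscaled inputs) per time step on a stratified, seeded 90/10 trial split and
reports held-out accuracy; steps with a single class in training are NaN.
A repeated-split mode reports mean ± sd, since a single split of ~50 test
trials is binomially noisy.

## Benchmark protocol

Per model class: `n_restarts` seeded fits (seeds `base_seed + i`), each
scored by one-step-ahead observation-space prediction R² on the validation
split (mean per-trial Euclidean R² for Gaussian, deviance R² for counts);
the best restart advances.  One-step selection was chosen because the
selection metric is least contaminated by rollout noise at the shortest
horizon.  Comparisons use the two-sided Wilcoxon signed-rank test on
per-trial paired metrics (Pratt handling of zero differences; p = 1 and no
advantage when all differences vanish), one row per metric and horizon, with
no correction across horizons (raw p-values are reported).  Fit-quality
histograms align and score *every* restart, not just the winner.

## Problem sizes in the shipped tests

The reference Gaussian comparison (250 trials, 5 dims, variance 0.01) runs
at 8 restarts per family with 300 EM iterations for the 3-mode model and 80
for the LDS; it completes in a few minutes and selects an excellent model
for essentially every seed.  The Poisson comparison and the fit-quality
histograms are run at reduced scale (fewer units and restarts than the
reference analysis, sizes stated in the tests themselves) so the whole suite
stays desk-scale; the pipeline accepts the full-scale settings unchanged for
anyone wanting the long run.

## Known limitations

* Poisson ELBO values are second-order approximations; they are comparable
  across models on the same data but are not guaranteed monotone per
  iteration, and the Laplace filter's log-likelihood is approximate for
  K > 1 or Poisson data.
* Variational EM on count data has a genuine entrapment problem: with weak
  per-bin likelihoods the mode structure can collapse toward a single
  averaged regime (a local optimum of the bound).  The k-means-seeded
  responsibilities and smoothed initialization mitigate but do not eliminate
  it; multi-restart selection is essential, and fit quality at low rates or
  few units is accordingly mixed.
* Alignment requires equal latent dimensions; no Procrustes-style partial
  alignment is attempted.
* The assumed-density filter collapses the mode-conditional mixture to one
  Gaussian per step; for strongly multimodal filtered states a mixture
  filter would be more faithful.
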