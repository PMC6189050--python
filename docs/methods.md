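# Methods

`dynclicks` models a two-alternative auditory decision task in a *dynamic*
environment and the inference strategies appropriate to it.  This note
documents the models, the numerical choices, the synthetic-data generator's
scope, and the limitations we know about.

## Task model

A hidden binary state S¹/S² follows a telegraph process with hazard rate
*h* (default 1 Hz): exponential holding times, equiprobable initial state.
Each side plays Poisson clicks whose rate toggles with the state between a
high rate r₁ and a low rate r₂.  Defaults put r₁ + r₂ = 40 Hz with
log(r₁/r₂) = 3, i.e. r₁ ≈ 38.1 Hz, r₂ ≈ 1.9 Hz.  The subject must report
the state at the moment the stimulus ends; stimulus durations are drawn
uniformly on 0.5–2 s (the source protocol states only the range; uniform is
the simplest consistent choice).  Sensory noise is modelled as per-click
mislocalization: each click is attributed to the wrong side independently
with probability *n*; *n* = 0.35 is the average level estimated for rats on
the static version of the task.

State trajectories are sampled with exact exponential inter-switch times
(a per-timestep Bernoulli sampler is retained as a finite-dt oracle), and
clicks by Poisson thinning at the ceiling rate r₁.  All randomness derives
from per-trial counter-based substreams `SeedSequence([seed, stream,
trial_id])`, so datasets are bit-reproducible and independent of generation
order, and mislocalization noise never aliases the stream that generated
the clicks.

## Optimal inference and its linear approximation

A single click on the fast side multiplies the posterior odds of the state
by e^κ, with

κ(r₁, r₂, n) = log[(r₁(1−n) + r₂n) / (r₂(1−n) + r₁n)],

which reduces to log(r₁/r₂) without noise, vanishes at n = ½, and flips
sign at n = 1.  In the continuum limit the log-odds â obey
dâ = κ(δ_R − δ_L) − 2h·sinh(â)dt; rescaling a = â/κ puts the accumulator in
units of clicks:

da = δ_R − δ_L − (2h/κ)·sinh(κa) dt.

Three implementations cross-check one another:

* the discrete Bayesian recursion on the odds ratio (log-space, with
  `logaddexp` for stability) — the ground truth for the ODE;
* grid Euler integration of the sinh ODE, decay step first, clicks added
  as unit impulses in their floor(t/dt) bin (simultaneous left+right clicks
  cancel, carrying zero evidence);
* exact event-driven propagation using the closed form
  tanh(κa/2)(t) = tanh(κa₀/2)·e^{−2ht} between clicks, which is
  discretization-free, unconditionally stable, and used for batch terminal
  decisions.  The same closed form drives the batch trajectory helper,
  because explicit Euler of the sinh term diverges at coarse steps.

The discrete recursion and the ODE agree to first order in dt; the
agreement constant grows like h·dt·e^{|â|}, so the tightest checks are run
at the average-noise κ ≈ 0.56 where |â| stays moderate.  Decisions are
sign(a) at stimulus end; exact zeros (equal effective click counts) are
broken by a fair coin from the trial's own substream.

The linear discounting agent da = δ_R − δ_L − λa dt is evaluated in closed
form, a(T) = Σ ±e^{−λ(T−t_click)}.  The accuracy-maximizing λ is found on a
fixed trial set (common random numbers, ties scored ½) by a coarse grid on
0–40 s⁻¹ (step 0.5) followed by bounded scalar refinement around the grid
argmax.  Reported behaviors at the study conditions: λ* ≈ 21 s⁻¹ with no
sensory noise, falling to ≈ 4 s⁻¹ at n = 0.35; the tuned linear agent is
within a fraction of a percentage point of the nonlinear agent's accuracy
and agrees with it on ≈ 97% of trials.

## Reverse correlation

Click trains are smoothed with a causal half-Gaussian (SD 5 ms, truncated
at 4 SDs, renormalized to unit mass) on a 1 ms grid.  The *excess rate*
subtracts the expectation of the **smoothed** rate given the generative
state trajectory (the instantaneous ±(r₁−r₂) filtered through the same
kernel).  This matters: subtracting the unfiltered instantaneous
expectation leaves a switch-locked transient that correlates with choice
and inflates the recovered discounting rate by ~40%.  Curves are aligned to
stimulus end on the window [−0.5, 0] s (the shortest trial length) — a
discounting agent's evidence weight depends on time until the decision, so
end alignment is the frame in which the curve is a single exponential
across variable-duration trials.  Choice-conditioned means are normalized
to unit area (making them lapse-invariant effective weights) and fit with
a·e^{bt} by least squares on a linear scale, excluding the last 2 kernel
SDs.  One mechanical edge effect is documented: the final grid sample's bin
is on average half-exposed (the grid end overshoots the true duration half
the time), so the last millisecond of the curve is biased; it lies inside
the excluded edge region.

For *recovering* a generative λ the package provides a dedicated estimator
(`recovery_fit`) with three deviations from the per-curve convention, each
forced by measurement:

1. **Sign-folded pooling.**  The mean over all trials of choice·e_i(t),
   normalized once — the efficient symmetric statistic — rather than two
   separately normalized per-choice curves.
2. **30 ms end exclusion.**  A click within a few tens of ms of stimulus
   end carries weight e^{−λ·lag} ≈ 1; a unit-weight click saturates its
   influence on the choice (the probability response is linear only in
   small weights), compressing the curve tail and biasing a plain
   exponential fit downward by ~30% at λ = 30 s⁻¹ — an asymptotic bias,
   verified at 60k trials.  Excluding the saturated region (all lags where
   e^{−λ·lag} > 0.4 for the λ range studied) removes it.
3. **Bootstrap CIs.**  Fit-covariance CIs under-cover 2–3× here because
   every trial contributes to the whole curve, correlating the noise across
   timepoints; the CI is instead b̂ ± 1.96·SD over 200 trial bootstraps.

With this estimator, generative λ ∈ {0, …, 30} s⁻¹ are recovered within
their 95% CIs on 20k-trial datasets, and b̂ is strictly increasing in λ.
At these sample sizes the honest uncertainty at large λ is wide (± ~5–7
s⁻¹): with λ = 30 the integration window holds roughly one click, so the
curve carries little information — a limitation of the method, not of the
implementation.

A noiseless perfect integrator in a *static* environment is nearly always
correct, so its choice-triggered signal is vanishingly small and a
"flat-curve" check on it is noise-dominated at any practical trial count;
flatness of the λ = 0 curve is instead demonstrated in the dynamic
environment (where accuracy ~75% leaves a usable selection signal) and by
contrast with a discounting agent.

## Trial-by-trial accumulator model

The behavioral model adds, to linear discounting, per-click multiplicative
sensory noise (variance σ_s² per unit adaptation weight), sensory
adaptation C (gain ϕ per click — depression below 1, facilitation above —
recovering to 1 with time constant τ_ϕ; the weight applied to a click is
the pre-multiplication value, C(0) = 1), accumulator diffusion σ_a²,
initial spread σ_i², a decision bias B and a lapse rate.  Without absorbing
bounds the accumulation density stays Gaussian with

μ(T) = Σ ±C_i e^{−λ(T−t_i)},
σ²(T) = σ_i²e^{−2λT} + σ_a²(1−e^{−2λT})/(2λ) + σ_s² Σ C_i e^{−2λ(T−t_i)},

using the λ > 0 = leak convention throughout, and σ_a²T as the λ → 0 limit.
The per-click noise variance scales linearly with C; consistently, the
generative model (and the tests' Euler–Maruyama oracle) draws each click's
registered amplitude from N(C, σ_s²·C).  P(go right) is the Gaussian mass
above B, mixed with symmetric lapse guessing P' = lapse/2 + (1−lapse)P.
The model's implied mislocalization probability is the Gaussian mass of a
click's amplitude below zero at the dataset-average adaptation ⟨C⟩,
n = ½(1 + erf(−⟨C⟩/√(2σ_s²⟨C⟩))).

Fitting maximizes the penalized likelihood of the recorded choices with
half-Gaussian priors on σ_i and σ_a (default scale 1 in clicks and
clicks/√s; the antecedent literature sets these from earlier fits without
printing values).  The negative log-likelihood and its *exact analytic
gradient* — chained through the moments and the adaptation recursion, whose
ϕ- and τ_ϕ-sensitivities propagate through the same linear recursion as C —
are evaluated on padded arrays, making a gradient evaluation a small
multiple of a likelihood evaluation.  Optimization is bounded L-BFGS-B
(λ ∈ [0,40], variances ∈ [0,50], ϕ ∈ (0,5], τ_ϕ ∈ [5 ms, 1 s],
B ∈ [−5,5], lapse ∈ [0,0.5]) from Latin-hypercube starts (default 8).
Uncertainty comes from the central-finite-difference Hessian (relative step
10⁻⁴) at the optimum: inverse as covariance, pseudo-inverse with a flag
when near-singular, ±1.96·√diag as CIs, and the eigen-decomposition exposed
for trade-off analysis.

On 20k simulated choices at rat-like parameters the discounting rate, bias
and lapse recover within their CIs; σ_a² and σ_i² shrink toward the prior
(they are weakly identified at strong discounting — the accumulator
forgets its starting point and diffusion within ~1/λ), and ϕ/τ_ϕ trade off
broadly.  Freezing all parameters but λ and maximizing expected accuracy
against the true terminal states reproduces the fitted λ to within a few
s⁻¹ and improves accuracy by far less than one percentage point.  Block-wise
1-D λ fits (default 7500 trials per block; profile NLL scanned on a coarse
grid before local refinement, because it can develop a shallow secondary
dip at very large λ) track a mid-dataset change in the generative rate
within one to two blocks.

## Problem sizes and defaults

Defaults follow the study conditions: 30k-trial training and test sets for
the λ optimization and agent comparison, 20k-trial datasets for reverse
correlation and model recovery, 7500-trial blocks for the environment-
switch analysis.  The test suite shares one 30k/30k agent comparison and
one 20k-trial model fit across all tests that need them; smaller sets
(2–8k) are used where a property is resolvable at that scale, with
tolerances set from the measured sampling variability.  The simulation grid
dt = 10⁻⁴ s satisfies r·dt ≪ 1 and h·dt ≪ 1 with an order of magnitude to
spare; reverse correlation runs on a 1 ms grid.

## What the generator does and does not emulate

The synthetic data reproduce the stimulus statistics (telegraph state,
state-conditional Poisson clicks, uniform durations, click
mislocalization) and, for recovery experiments, choices sampled from the
accumulator model's own probabilities.  They do not emulate training
dynamics, session structure, motivation or bias-correction trial selection,
slow non-stationarities in real subjects, or sensory noise mechanisms other
than mislocalization (amplitude noise and missed clicks are represented
only through their net effect on the effective mislocalization
probability).  Passing tests therefore demonstrate correctness of the
inference, measurement and fitting machinery under the stated generative
model — not that real subjects satisfy that model.

## Known limitations

* Reverse-correlation rate estimates saturate at strong discounting unless
  the end-saturated region is excluded; even then, uncertainty grows
  rapidly for λ ≳ 20 s⁻¹ at 20k trials.
* σ_a² and σ_i² are essentially unidentifiable at strong discounting and
  are reported as prior-regularized values, matching the mixed
  model-selection evidence in the antecedent literature.
* The Hessian-based CIs assume a locally quadratic likelihood; at parameter
  bounds (e.g. a variance fit to 0) the one-sided curvature makes them
  approximate, and the pseudo-inverse fallback is flagged in the result.
* The nonlinear agent's grid-Euler form is accurate but conditionally
  stable; the event-driven closed form is preferred for anything at coarse
  resolution.
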