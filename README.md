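# dynclicks

Evidence accumulation and discounting in a **dynamic Poisson-clicks task**:
simulation, normative inference, psychophysical reverse correlation, and
trial-by-trial behavioral model fitting.

In the task, a hidden binary state follows a telegraph process with hazard
rate *h*; each side plays Poisson clicks whose rates (r₁ high, r₂ low, with
r₁ + r₂ = 40 Hz) swap with the state, and the subject must report the state
at the moment the stimulus ends.  Because old clicks stop being informative
once the state may have switched, the ideal observer *discounts* old
evidence.  This package is for computational and behavioral neuroscientists
who want to simulate such tasks, compute the optimal strategy under sensory
noise, measure integration timescales from choices, and fit accumulator
models to trial-by-trial behavior.

## The models

**Optimal inference.**  Writing a for the accumulated evidence in units of
clicks and κ for the log-likelihood ratio carried by one click,

    da = δ_R − δ_L − (2h/κ) sinh(κa) dt,
    κ(r₁, r₂, n) = log[(r₁(1−n) + r₂n) / (r₂(1−n) + r₁n)],

where δ_R, δ_L are the click trains and n is the probability that a click
is heard on the wrong side.  Noise makes clicks less reliable (κ = 0 at
n = ½), which weakens the optimal discounting and lengthens the optimal
integration timescale.

**Linear approximation.**  The leaky integrator
da = δ_R − δ_L − λa dt, with the discounting rate λ tuned for accuracy,
performs nearly identically to the full nonlinear rule at the study's
click rates; 1/λ is the integration timescale.

**Measurement.**  Psychophysical reverse correlation — the choice-triggered
average of the excess (smoothed, state-expectation-subtracted) click rate,
normalized to unit area — recovers λ through an exponential fit a·e^{bt}.

**Trial-by-trial model.**  A Gaussian accumulator with linear discounting,
per-click sensory noise, click-rate adaptation, diffusion, initial noise,
bias and lapse; its closed-form choice likelihood is maximized per subject,
with inverse-Hessian uncertainty.

## Worked example

```python
import dataclasses
import dynclicks as dc

cfg = dc.TaskConfig(seed=11)             # h = 1 Hz, rates ≈ 38.1/1.9 Hz
train = dc.generate_trials(cfg, 15_000)
test = dc.generate_trials(dataclasses.replace(cfg, seed=12), 15_000,
                          start_id=15_000)

# average rat-level sensory noise: flip each click with p = 0.35
noisy_train = dc.mislocalize_trials(train, 0.35, seed=101)
noisy_test = dc.mislocalize_trials(test, 0.35, seed=102)

lam_star, grid, acc = dc.optimize_lambda(noisy_train)
kap = dc.kappa(cfg.rate_high, cfg.rate_low, 0.35)
res = dc.compare_linear_nonlinear(noisy_test, cfg.hazard_rate, kap, lam_star)
print(f"lambda* = {lam_star:.2f}/s")
print(f"linear {res.acc_linear:.4f}, nonlinear {res.acc_nonlinear:.4f}, "
      f"agreement {res.agreement:.4f}")
```

prints

```
lambda* = 3.72/s
linear 0.7638, nonlinear 0.7664, agreement 0.9735
```

— the accuracy-maximizing linear discounting rate on the noisy training
set is ≈ 3.7 s⁻¹ (an integration timescale of ≈ 270 ms); on held-out
trials the tuned linear agent reaches 76.4% accuracy versus 76.6% for the
full nonlinear rule (99.7% of its accuracy), and the two make the same
choice on 97.4% of trials — the linear approximation is effectively
equivalent at these task statistics.

A command-line interface mirrors the library
(`dynclicks simulate|kappa|agents run|optimize-lambda|revcor|fit|recover|blocks|experiment`);
every run is reproducible from its `--seed`, and the `experiment`
subcommands write CSV tables plus a manifest with the spec and output
hashes.

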