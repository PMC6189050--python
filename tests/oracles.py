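"""Independent reference implementations used only by the tests.

These deliberately avoid the package's analytic shortcuts: brute-force
Euler(–Maruyama) stepping and a black-box ODE integrator, so agreement with
the library is informative.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from dynclicks.accumulator import AccumulatorParams, adaptation_trace
from dynclicks.agents import merged_clicks
from dynclicks.task import Trial


def sinh_decay_reference(a0: float, h: float, kappa: float,
                         t_eval: np.ndarray) -> np.ndarray:
    """High-accuracy adaptive integration of da/dt = −(2h/κ)sinh(κa)."""
    sol = solve_ivp(lambda t, a: -(2.0 * h / kappa) * np.sinh(kappa * a),
                    (0.0, float(t_eval[-1])), [a0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    return sol.y[0]


def linear_agent_euler(trial: Trial, lam: float, dt: float) -> np.ndarray:
    """Explicit Euler for the leaky integrator, clicks as bin impulses."""
    n_steps = int(round(trial.duration / dt))
    net = np.zeros(n_steps)
    for clicks, sign in ((trial.right_clicks, 1.0), (trial.left_clicks, -1.0)):
        idx = np.minimum(np.floor(clicks / dt).astype(int), n_steps - 1)
        np.add.at(net, idx, sign)
    a = np.empty(n_steps + 1)
    a[0] = 0.0
    x = 0.0
    for k in range(n_steps):
        x = x - lam * x * dt + net[k]
        a[k + 1] = x
    return a


def euler_maruyama_moments(trial: Trial, params: AccumulatorParams,
                           n_paths: int = 200_000, dt: float = 2e-4,
                           seed: int = 0) -> tuple[float, float, float, float]:
    """Monte-Carlo (mean, var, se_mean, se_var) of the accumulator SDE.

    Each click's registered amplitude is drawn N(C, σ_s²·C) — the generative
    model whose closed-form moments the library computes.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(trial.duration / dt))
    ct, cs = merged_clicks(trial)
    C = adaptation_trace(ct, params.phi, params.tau_phi)
    bins = np.minimum((ct / dt).astype(int), n_steps - 1)
    per_bin: dict[int, list[tuple[float, float]]] = {}
    for b, s, c in zip(bins, cs, C):
        per_bin.setdefault(int(b), []).append((s, c))
    a = np.sqrt(params.sigma_i2) * rng.standard_normal(n_paths)
    sd_step = np.sqrt(params.sigma_a2 * dt)
    for k in range(n_steps):
        a += -params.lam * a * dt + sd_step * rng.standard_normal(n_paths)
        for s, c in per_bin.get(k, ()):
            a += s * (c + np.sqrt(params.sigma_s2 * c) * rng.standard_normal(n_paths))
    mean = float(a.mean())
    var = float(a.var())
    se_mean = float(a.std() / np.sqrt(n_paths))
    se_var = float(var * np.sqrt(2.0 / n_paths))
    return mean, var, se_mean, se_var
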