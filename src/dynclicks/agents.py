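"""Normative inference agents for the dynamic clicks task.

Three equivalent descriptions of the ideal observer, plus its linear
approximation:

* ``discrete_posterior`` — the exact discrete-time Bayesian update of the
  posterior odds R_t of the two hidden states, combining the per-bin click
  likelihood ratio with the telegraph transition kernel.
* ``nonlinear_agent`` — the continuum limit in units of clicks:
  da = δ_R − δ_L − (2h/κ) sinh(κa) dt.  Clicks add ±1; accumulated evidence
  is discounted at a rate set by the environment volatility h and the
  per-click reliability κ.
* ``nonlinear_terminal`` — the same agent propagated exactly between clicks
  using the closed form tanh(κa/2)(t) = tanh(κa₀/2)·e^{−2ht}, which makes
  batch evaluation of terminal decisions cheap and discretization-free.
* ``linear_agent`` — the leaky integrator da = δ_R − δ_L − λa dt, the best
  linear stand-in for the sinh discounting function, with closed-form
  solution a(t) = Σ_clicks ±e^{−λ(t − t_click)}.

Decisions are sign(a) at stimulus end; exact ties are broken by a fair coin
from the trial's own random substream so runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .task import S1, RIGHT, LEFT, Trial, trial_rng, _STREAM_CHOICE


@dataclass
class AgentTrajectory:
    """Time course of one agent on one trial.

    ``a`` is in clicks units for the sinh/linear agents and in log-odds for
    the discrete recursion.  ``choice`` is the side favored at the end
    (ties resolved by coin flip); ``com_times`` are the change-of-mind times
    (grid times where sign(a) flips).
    """

    times: np.ndarray
    a: np.ndarray
    choice: str
    com_times: np.ndarray


def merged_clicks(trial: Trial) -> tuple[np.ndarray, np.ndarray]:
    """Time-sorted merged click train as (times, signs): +1 right, −1 left."""
    times = np.concatenate([trial.right_clicks, trial.left_clicks])
    signs = np.concatenate([
        np.ones(trial.right_clicks.size),
        -np.ones(trial.left_clicks.size),
    ])
    order = np.argsort(times, kind="stable")
    return times[order], signs[order]


def _grid(duration: float, dt: float) -> np.ndarray:
    n_steps = int(round(duration / dt))
    return np.arange(n_steps + 1) * dt


def _bin_impulses(trial: Trial, n_steps: int, dt: float) -> np.ndarray:
    """Net click impulse per grid bin; simultaneous L/R in a bin cancel."""
    net = np.zeros(n_steps)
    for clicks, sign in ((trial.right_clicks, 1.0), (trial.left_clicks, -1.0)):
        idx = np.minimum(np.floor(clicks / dt).astype(int), n_steps - 1)
        np.add.at(net, idx, sign)
    return net


def _decide(a_final: float, trial: Trial, seed: int = 0) -> str:
    if a_final > 0:
        return RIGHT
    if a_final < 0:
        return LEFT
    rng = trial_rng(seed, trial.trial_id, _STREAM_CHOICE)
    return RIGHT if rng.random() < 0.5 else LEFT


def _com_from_grid(times: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Grid times where the favored side flips (zeros carry the last sign)."""
    s = np.sign(a)
    # forward-fill zero signs with the preceding nonzero sign
    filled = s.copy()
    for k in range(1, filled.size):
        if filled[k] == 0:
            filled[k] = filled[k - 1]
    flips = np.nonzero(filled[1:] * filled[:-1] < 0)[0] + 1
    return times[flips]


# ---------------------------------------------------------------------------
# discrete Bayesian recursion (log posterior odds)
# ---------------------------------------------------------------------------

def discrete_posterior(trial: Trial, h: float, kappa: float, dt: float = 1e-4,
                       seed: int = 0) -> AgentTrajectory:
    """Exact discrete-time posterior log-odds of the hidden state.

    Each bin multiplies the prior odds by the transition-mixed odds
    ((1−hΔt)R + hΔt) / (hΔt·R + 1−hΔt) and by the bin's click likelihood
    ratio (e^{±κ} for a single-side click, 1 for none or both).  Serves as
    the ground-truth oracle for the sinh ODE agent.
    """
    if h * dt >= 0.05:
        raise ValueError("dt too coarse for the discrete recursion: need h*dt << 1")
    n_steps = int(round(trial.duration / dt))
    net = _bin_impulses(trial, n_steps, dt)
    log_r = np.empty(n_steps + 1)
    log_r[0] = 0.0
    ell = 0.0
    if h > 0:
        log_stay = math.log1p(-h * dt)
        log_switch = math.log(h * dt)
        for k in range(n_steps):
            num = np.logaddexp(log_stay + ell, log_switch)
            den = np.logaddexp(log_switch + ell, log_stay)
            ell = kappa * net[k] + num - den
            log_r[k + 1] = ell
    else:
        log_r[1:] = kappa * np.cumsum(net)
    times = _grid(trial.duration, dt)
    return AgentTrajectory(times, log_r, _decide(log_r[-1], trial, seed),
                           _com_from_grid(times, log_r))


# ---------------------------------------------------------------------------
# nonlinear (sinh) discounting agent, clicks units
# ---------------------------------------------------------------------------

def nonlinear_agent(trial: Trial, h: float, kappa: float, dt: float = 1e-4,
                    a0: float = 0.0, seed: int = 0) -> AgentTrajectory:
    """Euler integration of da = δ_R − δ_L − (2h/κ)sinh(κa)dt on the dt grid.

    Clicks enter as unit impulses added after the decay step of their bin
    (bin = floor(t/dt)); simultaneous left+right clicks cancel.  At κ = 0
    the discounting term is replaced by its limit −2h·a.
    """
    if not np.isfinite(a0):
        raise ValueError("a0 must be finite")
    n_steps = int(round(trial.duration / dt))
    net = _bin_impulses(trial, n_steps, dt)
    a = np.empty(n_steps + 1)
    a[0] = a0
    x = a0
    if kappa == 0.0:
        for k in range(n_steps):
            x = x - 2.0 * h * x * dt + net[k]
            a[k + 1] = x
    else:
        c = 2.0 * h / kappa
        for k in range(n_steps):
            x = x - c * math.sinh(kappa * x) * dt + net[k]
            a[k + 1] = x
    times = _grid(trial.duration, dt)
    return AgentTrajectory(times, a, _decide(a[-1], trial, seed),
                           _com_from_grid(times, a))


def _sinh_decay(a: np.ndarray, gap: np.ndarray, h: float, kappa: float) -> np.ndarray:
    """Exact relaxation of da/dt = −(2h/κ)sinh(κa) over time gaps.

    tanh(κa/2) decays exponentially at rate 2h, which follows from
    d/dt log tanh(κa/2) = −2h along solutions.
    """
    if h == 0.0:
        return a
    if kappa == 0.0:
        return a * np.exp(-2.0 * h * gap)
    th = np.tanh(0.5 * kappa * a) * np.exp(-2.0 * h * gap)
    out = (2.0 / kappa) * np.arctanh(th)
    # zero gap (simultaneous clicks) must be an exact no-op even where tanh saturates
    return np.where(gap > 0.0, out, a)


def nonlinear_terminal(trials: list[Trial], h: float, kappa: float,
                       a0: float = 0.0) -> np.ndarray:
    """Terminal accumulator value of the sinh agent on each trial.

    Exact event-driven propagation (no time grid): decay between clicks via
    :func:`_sinh_decay`, ±1 jumps at clicks.  Vectorized across trials by
    padding click trains to the longest one.
    """
    n = len(trials)
    counts = [t.right_clicks.size + t.left_clicks.size for t in trials]
    kmax = max(counts) if counts else 0
    times = np.zeros((n, kmax))
    signs = np.zeros((n, kmax))
    durations = np.array([t.duration for t in trials])
    for i, trial in enumerate(trials):
        ct, cs = merged_clicks(trial)
        times[i, :ct.size] = ct
        times[i, ct.size:] = trial.duration  # padding: zero-sign events at the end
        signs[i, :cs.size] = cs
    a = np.full(n, float(a0))
    prev = np.zeros(n)
    for k in range(kmax):
        a = _sinh_decay(a, times[:, k] - prev, h, kappa)
        a = a + signs[:, k]
        prev = times[:, k]
    return _sinh_decay(a, durations - prev, h, kappa)


def nonlinear_trajectories(trials: list[Trial], h: float, kappa: float,
                           dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Grid trajectories of the sinh agent for a batch of trials.

    Each step applies the exact between-click relaxation (:func:`_sinh_decay`,
    stable at any step size, unlike explicit Euler whose sinh term diverges
    at coarse dt) followed by the bin's click impulses.  Rows are trials on
    one shared grid; NaN beyond each trial's end.  Used for ensemble
    analyses such as change-of-mind timing.
    """
    durations = np.array([t.duration for t in trials])
    n_steps = int(round(durations.max() / dt))
    n = len(trials)
    net = np.zeros((n, n_steps))
    for i, trial in enumerate(trials):
        steps_i = int(round(trial.duration / dt))
        net[i, :steps_i] = _bin_impulses(trial, steps_i, dt)
    a = np.zeros((n, n_steps + 1))
    x = np.zeros(n)
    gap = np.full(n, dt)
    for k in range(n_steps):
        x = _sinh_decay(x, gap, h, kappa) + net[:, k]
        a[:, k + 1] = x
    times = np.arange(n_steps + 1) * dt
    a[times[None, :] > durations[:, None] + 0.5 * dt] = np.nan
    return times, a


# ---------------------------------------------------------------------------
# linear discounting agent
# ---------------------------------------------------------------------------

def linear_agent(trial: Trial, lam: float, dt: float = 1e-4, seed: int = 0) -> AgentTrajectory:
    """Leaky integrator da = δ_R − δ_L − λa dt, solved in closed form.

    a(t) = Σ_right e^{−λ(t−t_i)} − Σ_left e^{−λ(t−t_j)} over clicks at or
    before t, starting from a(0) = 0.
    """
    if lam < 0:
        raise ValueError(f"discounting rate must be >= 0, got {lam}")
    times = _grid(trial.duration, dt)
    ct, cs = merged_clicks(trial)
    lag = times[:, None] - ct[None, :]
    with np.errstate(over="ignore"):
        contrib = np.where(lag >= 0, np.exp(-lam * np.maximum(lag, 0.0)), 0.0)
    a = contrib @ cs
    return AgentTrajectory(times, a, _decide(a[-1], trial, seed),
                           _com_from_grid(times, a))


def linear_terminal(trials: list[Trial], lam: float) -> np.ndarray:
    """Closed-form terminal value of the linear agent on each trial."""
    if lam < 0:
        raise ValueError(f"discounting rate must be >= 0, got {lam}")
    idx, lags, signs = _flat_clicks(trials)
    w = signs * np.exp(-lam * lags)
    return np.bincount(idx, weights=w, minlength=len(trials))


def _flat_clicks(trials: list[Trial]):
    """Flatten datasets for vectorized terminal-value evaluation."""
    idx, lags, signs = [], [], []
    for i, trial in enumerate(trials):
        ct, cs = merged_clicks(trial)
        idx.append(np.full(ct.size, i))
        lags.append(trial.duration - ct)
        signs.append(cs)
    return (np.concatenate(idx).astype(int), np.concatenate(lags),
            np.concatenate(signs))


# ---------------------------------------------------------------------------
# choices, accuracy, λ optimization
# ---------------------------------------------------------------------------

def decide_terminal(a_final: np.ndarray, trials: list[Trial], seed: int = 0) -> np.ndarray:
    """Choices (+1 right, −1 left) from terminal values; coin-flip ties."""
    choice = np.sign(a_final)
    for i in np.nonzero(choice == 0)[0]:
        rng = trial_rng(seed, trials[i].trial_id, _STREAM_CHOICE)
        choice[i] = 1.0 if rng.random() < 0.5 else -1.0
    return choice


def state_signs(trials: list[Trial]) -> np.ndarray:
    """Terminal hidden state of each trial as +1 (S1/right) or −1 (S2/left)."""
    return np.array([1.0 if t.final_state == S1 else -1.0 for t in trials])


def accuracy(choices: np.ndarray, trials: list[Trial]) -> float:
    """Fraction of trials whose choice matches the terminal hidden state."""
    return float(np.mean(choices == state_signs(trials)))


def optimize_lambda(trials: list[Trial], lambda_grid: np.ndarray | None = None,
                    refine: bool = True) -> tuple[float, np.ndarray, np.ndarray]:
    """Discounting rate that maximizes terminal-state prediction accuracy.

    Accuracy(λ) is evaluated on one fixed trial set (common random numbers)
    with exact ties scored as 1/2, so the objective is deterministic in λ.
    A coarse grid (default 0–40 /s, step 0.5) is followed by bounded scalar
    refinement around the grid argmax; grid ties break toward smaller λ.

    Returns (λ*, grid, accuracy-on-grid).
    """
    if not trials:
        raise ValueError("empty trial set")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 40.0 + 1e-9, 0.5)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    idx, lags, signs = _flat_clicks(trials)
    truth = state_signs(trials)
    n = len(trials)

    def acc(lam: float) -> float:
        a_t = np.bincount(idx, weights=signs * np.exp(-lam * lags), minlength=n)
        score = np.where(a_t == 0, 0.5, (np.sign(a_t) == truth).astype(float))
        return float(np.mean(score))

    curve = np.array([acc(lam) for lam in lambda_grid])
    best = int(np.argmax(curve))
    lam_star = float(lambda_grid[best])
    if refine and lambda_grid.size > 1:
        step = lambda_grid[min(best + 1, lambda_grid.size - 1)] - lambda_grid[max(best - 1, 0)]
        lo = max(lambda_grid[0], lam_star - step)
        hi = min(lambda_grid[-1], lam_star + step)
        res = minimize_scalar(lambda lam: -acc(lam), bounds=(lo, hi), method="bounded")
        if -res.fun >= curve[best]:
            lam_star = float(res.x)
    return lam_star, lambda_grid, curve


@dataclass
class LinearNonlinearComparison:
    acc_linear: float
    acc_nonlinear: float
    agreement: float

    @property
    def accuracy_ratio(self) -> float:
        return self.acc_linear / self.acc_nonlinear


def compare_linear_nonlinear(trials: list[Trial], h: float, kappa: float,
                             lam: float, seed: int = 0) -> LinearNonlinearComparison:
    """Accuracies and trial-by-trial choice agreement of the two agents.

    Both agents receive the *same* click trains (same noise realization), so
    the comparison isolates the discounting nonlinearity.
    """
    a_lin = linear_terminal(trials, lam)
    a_non = nonlinear_terminal(trials, h, kappa)
    c_lin = decide_terminal(a_lin, trials, seed)
    c_non = decide_terminal(a_non, trials, seed)
    return LinearNonlinearComparison(
        acc_linear=accuracy(c_lin, trials),
        acc_nonlinear=accuracy(c_non, trials),
        agreement=float(np.mean(c_lin == c_non)),
    )


# ---------------------------------------------------------------------------
# changes of mind
# ---------------------------------------------------------------------------

def changes_of_mind(trajectory: AgentTrajectory, switch_times: np.ndarray) -> np.ndarray:
    """Offsets of accumulator sign flips from the latest hidden-state switch.

    Returns t_com − t_last_switch for every change of mind that has at least
    one state switch before it; flips before the first switch are dropped
    (they have no triggering state change to align to).
    """
    switch_times = np.asarray(switch_times, dtype=float)
    offsets = []
    for t_com in trajectory.com_times:
        k = int(np.searchsorted(switch_times, t_com, side="right"))
        if k > 0:
            offsets.append(t_com - switch_times[k - 1])
    return np.asarray(offsets)


def com_offsets_ensemble(trials: list[Trial], h: float, kappa: float,
                         dt: float = 1e-3) -> np.ndarray:
    """Pooled change-of-mind offsets of the sinh agent over a trial set."""
    times, a = nonlinear_trajectories(trials, h, kappa, dt)
    out = []
    for i, trial in enumerate(trials):
        row = a[i]
        valid = ~np.isnan(row)
        traj = AgentTrajectory(times[valid], row[valid], RIGHT,
                               _com_from_grid(times[valid], row[valid]))
        out.append(changes_of_mind(traj, trial.switch_times))
    return np.concatenate(out) if out else np.zeros(0)


def com_histogram(offsets: np.ndarray, bin_width: float = 0.05,
                  t_max: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (bin edges, normalized counts) of change-of-mind offsets."""
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, _ = np.histogram(offsets, bins=edges, density=True)
    return edges, counts
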