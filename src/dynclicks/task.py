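"""Synthetic dynamic-clicks trials.

The task: a hidden binary state (a telegraph process with hazard rate ``h``)
sets which of two speakers plays Poisson clicks at the high rate ``r1`` and
which at the low rate ``r2``.  In state S1 the right speaker is fast, in S2
the left speaker is fast.  The subject must report the state at the moment
the stimulus ends.  Sensory noise is modelled as per-click mislocalization:
each click is independently attributed to the wrong side with probability
``n``.

This module generates trials, applies mislocalization, and reads/writes
trial datasets as JSON-lines (one trial per line) plus a long-format CSV
exporter.  All randomness flows from a master seed through per-trial
substreams (``SeedSequence([master_seed, stream, trial_id])``) so datasets
are reproducible regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

RIGHT = "right"
LEFT = "left"
S1 = "S1"
S2 = "S2"

#: side rewarded for each terminal hidden state
STATE_TO_SIDE = {S1: RIGHT, S2: LEFT}

# substream tags, so that e.g. mislocalization noise never aliases
# the stream that generated the clicks of the same trial
_STREAM_TRIAL = 0
_STREAM_MISLOC = 1
_STREAM_CHOICE = 2


def trial_rng(seed: int, trial_id: int, stream: int = _STREAM_TRIAL) -> np.random.Generator:
    """Per-trial random substream: counter-based, order independent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), int(trial_id)]))


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters.

    Defaults are the study conditions: hazard 1 Hz, click rates summing to
    40 Hz with log ratio 3 (≈38.1/1.9 Hz), stimulus durations uniform on
    0.5–2 s, simulation grid 0.1 ms.
    """

    hazard_rate: float = 1.0
    rate_high: float = 40.0 * np.e**3 / (1.0 + np.e**3)   # ≈ 38.1 Hz
    rate_low: float = 40.0 / (1.0 + np.e**3)              # ≈ 1.9 Hz
    dur_min: float = 0.5
    dur_max: float = 2.0
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hazard_rate >= 0 and np.isfinite(self.hazard_rate)):
            raise ValueError(f"hazard_rate must be finite and >= 0, got {self.hazard_rate}")
        if not (self.rate_high > 0 and self.rate_low > 0):
            raise ValueError("click rates must be positive")
        if not self.rate_high > self.rate_low:
            raise ValueError("rate_high must exceed rate_low")
        if not (0 < self.dur_min <= self.dur_max):
            raise ValueError("need 0 < dur_min <= dur_max")
        if not (self.dt > 0 and max(self.rate_high, self.rate_low) * self.dt < 0.05
                and self.hazard_rate * self.dt < 0.05):
            raise ValueError("dt too coarse: need max(r1, r2)*dt < 0.05 and h*dt < 0.05")

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Trial:
    """One simulated stimulus.

    ``switch_times`` are the hidden-state toggles in (0, duration);
    ``correct_side`` is the side rewarded given the state at ``duration``.
    """

    trial_id: int
    duration: float
    initial_state: str
    switch_times: np.ndarray
    right_clicks: np.ndarray
    left_clicks: np.ndarray
    correct_side: str
    choice: str | None = None

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.right_clicks = np.asarray(self.right_clicks, dtype=float)
        self.left_clicks = np.asarray(self.left_clicks, dtype=float)

    def state_at(self, t: float) -> str:
        """Hidden state at time ``t`` (switch at exactly t counts as past)."""
        flips = int(np.searchsorted(self.switch_times, t, side="right"))
        if self.initial_state == S1:
            return S1 if flips % 2 == 0 else S2
        return S2 if flips % 2 == 0 else S1

    @property
    def final_state(self) -> str:
        return self.state_at(self.duration)


@dataclass
class NoisyTrial(Trial):
    """A trial after per-click mislocalization.

    ``flip_mask`` records, for the time-sorted merged click train of the
    source trial, which clicks changed side.  Click times are never altered,
    only side labels, so the merged multiset of times is preserved.
    """

    misloc_prob: float = 0.0
    flip_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def generate_state_trajectory(
    config: TaskConfig, duration: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Sample the telegraph hidden state for one trial.

    The initial state is equiprobable; inter-switch intervals are exact
    Exponential(h) draws (the continuum limit of per-timestep switching with
    probability h*dt).
    """
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError(f"duration must be finite and positive, got {duration}")
    initial_state = S1 if rng.random() < 0.5 else S2
    h = config.hazard_rate
    if h == 0:
        return initial_state, np.zeros(0)
    switches = []
    t = rng.exponential(1.0 / h)
    while t < duration:
        switches.append(t)
        t += rng.exponential(1.0 / h)
    return initial_state, np.asarray(switches)


def generate_state_trajectory_bernoulli(
    config: TaskConfig, duration: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Per-dt Bernoulli switching; oracle counterpart of the exact sampler."""
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError(f"duration must be finite and positive, got {duration}")
    initial_state = S1 if rng.random() < 0.5 else S2
    n_steps = int(np.floor(duration / config.dt))
    flips = rng.random(n_steps) < config.hazard_rate * config.dt
    switch_times = (np.nonzero(flips)[0] + 1) * config.dt
    return initial_state, switch_times


def _segments(initial_state: str, switch_times: np.ndarray, duration: float):
    """Yield (t0, t1, state) over the piecewise-constant state trajectory."""
    edges = np.concatenate([[0.0], switch_times, [duration]])
    state = initial_state
    for t0, t1 in zip(edges[:-1], edges[1:]):
        yield t0, t1, state
        state = S2 if state == S1 else S1


def generate_clicks(
    initial_state: str,
    switch_times: np.ndarray,
    duration: float,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the two click trains given a state trajectory.

    Each side is an inhomogeneous Poisson process whose rate toggles between
    r1 and r2 with the hidden state (right fast in S1, left fast in S2).
    Sampled by thinning: candidates at the ceiling rate r1 over the whole
    trial, kept with probability rate(t)/r1.
    """
    r1, r2 = config.rate_high, config.rate_low
    out = {}
    for side in (RIGHT, LEFT):
        n_cand = rng.poisson(r1 * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        keep = np.ones(n_cand, dtype=bool)
        u = rng.random(n_cand)
        for t0, t1, state in _segments(initial_state, switch_times, duration):
            fast = (state == S1 and side == RIGHT) or (state == S2 and side == LEFT)
            if not fast:
                in_seg = (cand >= t0) & (cand < t1)
                keep[in_seg] &= u[in_seg] < r2 / r1
        out[side] = cand[keep]
    return out[RIGHT], out[LEFT]


def generate_trial(config: TaskConfig, trial_id: int = 0,
                   rng: np.random.Generator | None = None) -> Trial:
    """Generate one trial: duration ~ U(dur_min, dur_max), telegraph state,
    state-conditional Poisson clicks, correct side from the terminal state."""
    if rng is None:
        rng = trial_rng(config.seed, trial_id)
    duration = rng.uniform(config.dur_min, config.dur_max)
    initial_state, switch_times = generate_state_trajectory(config, duration, rng)
    right_clicks, left_clicks = generate_clicks(
        initial_state, switch_times, duration, config, rng)
    trial = Trial(
        trial_id=trial_id,
        duration=duration,
        initial_state=initial_state,
        switch_times=switch_times,
        right_clicks=right_clicks,
        left_clicks=left_clicks,
        correct_side="",
    )
    trial.correct_side = STATE_TO_SIDE[trial.final_state]
    return trial


def generate_trials(config: TaskConfig, n_trials: int, start_id: int = 0) -> list[Trial]:
    """Generate a dataset; trial ``i`` depends only on (config.seed, i)."""
    return [generate_trial(config, trial_id=start_id + i) for i in range(n_trials)]


def mislocalize(trial: Trial, n: float, rng: np.random.Generator | None = None,
                seed: int | None = None) -> NoisyTrial:
    """Flip each click to the opposite side independently with probability n.

    Click times are untouched; only side labels change.  ``flip_mask`` is
    aligned with the time-sorted merged train (ties: right before left).
    """
    if not (0.0 <= n <= 1.0):
        raise ValueError(f"mislocalization probability must be in [0, 1], got {n}")
    if rng is None:
        rng = trial_rng(trial.trial_id if seed is None else seed, trial.trial_id,
                        _STREAM_MISLOC)
    times = np.concatenate([trial.right_clicks, trial.left_clicks])
    sides = np.concatenate([
        np.full(trial.right_clicks.size, True),   # True = right
        np.full(trial.left_clicks.size, False),
    ])
    order = np.argsort(times, kind="stable")
    times, sides = times[order], sides[order]
    flip = rng.random(times.size) < n
    new_sides = sides ^ flip
    return NoisyTrial(
        trial_id=trial.trial_id,
        duration=trial.duration,
        initial_state=trial.initial_state,
        switch_times=trial.switch_times.copy(),
        right_clicks=times[new_sides],
        left_clicks=times[~new_sides],
        correct_side=trial.correct_side,
        choice=trial.choice,
        misloc_prob=n,
        flip_mask=flip,
    )


def mislocalize_trials(trials: Sequence[Trial], n: float, seed: int) -> list[NoisyTrial]:
    """Mislocalize a dataset with per-trial substreams of ``seed``."""
    return [mislocalize(t, n, rng=trial_rng(seed, t.trial_id, _STREAM_MISLOC))
            for t in trials]


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("trial_id", "duration", "initial_state", "switch_times",
                  "right_clicks", "left_clicks", "correct_side")


def _trial_record(trial: Trial) -> dict:
    rec = {
        "trial_id": int(trial.trial_id),
        "duration": float(trial.duration),
        "initial_state": trial.initial_state,
        "switch_times": [float(t) for t in trial.switch_times],
        "right_clicks": [float(t) for t in trial.right_clicks],
        "left_clicks": [float(t) for t in trial.left_clicks],
        "correct_side": trial.correct_side,
    }
    if trial.choice is not None:
        rec["choice"] = trial.choice
    return rec


def write_trials(trials: Iterable[Trial], path) -> None:
    """Write trials as JSON-lines, one trial per line, keys in fixed order."""
    with open(path, "w") as fh:
        for trial in trials:
            fh.write(json.dumps(_trial_record(trial)) + "\n")


def read_trials(path) -> list[Trial]:
    """Read a JSON-lines trial dataset written by :func:`write_trials`."""
    trials: list[Trial] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed JSON ({exc})") from exc
            missing = [k for k in _REQUIRED_KEYS if k not in rec]
            if missing:
                raise ValueError(f"{path}: line {lineno}: missing keys {missing}")
            trials.append(Trial(
                trial_id=rec["trial_id"],
                duration=rec["duration"],
                initial_state=rec["initial_state"],
                switch_times=np.asarray(rec["switch_times"], dtype=float),
                right_clicks=np.asarray(rec["right_clicks"], dtype=float),
                left_clicks=np.asarray(rec["left_clicks"], dtype=float),
                correct_side=rec["correct_side"],
                choice=rec.get("choice"),
            ))
    return trials


def trials_to_events_csv(trials: Iterable[Trial], path) -> None:
    """Long-format export: one row per click or switch event."""
    rows = []
    for trial in trials:
        for t in trial.switch_times:
            rows.append((trial.trial_id, "switch", float(t), ""))
        for t in trial.right_clicks:
            rows.append((trial.trial_id, "click", float(t), RIGHT))
        for t in trial.left_clicks:
            rows.append((trial.trial_id, "click", float(t), LEFT))
    df = pd.DataFrame(rows, columns=["trial_id", "event", "time", "side"])
    df.sort_values(["trial_id", "time"], kind="stable").to_csv(path, index=False)
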