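"""Figure-level experiment orchestration.

Each experiment is fully determined by an :class:`ExperimentSpec` and its
seed: trial generation, mislocalization, agent simulation and fitting all
draw from substreams derived from the spec seed.  Outputs are plain CSV/JSON
plus a manifest recording the spec, seed and output hashes, so a run can be
reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .task import TaskConfig, generate_trials, mislocalize_trials
from .reliability import kappa
from .agents import (compare_linear_nonlinear, decide_terminal, linear_terminal,
                     optimize_lambda)
from .revcor import recovery_fit
from .accumulator import AccumulatorParams, fit_lambda_blocks, simulate_choices

logger = logging.getLogger(__name__)


def derive_seed(master: int, *tags: int) -> int:
    """Deterministic sub-seed (< 2^31) from a master seed and integer tags."""
    return int(np.random.SeedSequence([int(master), *map(int, tags)])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentSpec:
    """Everything needed to reproduce one experiment."""

    name: str
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0
    n_train: int = 30_000
    n_test: int = 30_000
    noise_levels: tuple[float, ...] = (0.0, 0.175, 0.35)
    lambdas: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = dataclasses.asdict(self.task)
        return d

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _write_manifest(spec: ExperimentSpec, outputs: dict[str, Path]) -> None:
    if spec.out_dir is None:
        return
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": spec.name,
        "spec": spec.to_dict(),
        "spec_hash": spec.spec_hash(),
        "seed": spec.seed,
        "version": __version__,
        "outputs": {k: {"path": str(p),
                        "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
                    for k, p in outputs.items()},
    }
    (out_dir / f"{spec.name}_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")


def _maybe_write(spec: ExperimentSpec, df: pd.DataFrame, stem: str) -> dict[str, Path]:
    if spec.out_dir is None:
        return {}
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.csv"
    df.to_csv(path, index=False)
    return {stem: path}


def run_noise_study(spec: ExperimentSpec) -> pd.DataFrame:
    """Sweep sensory-noise levels: best linear λ, both agents' accuracies,
    and their trial-by-trial agreement on shared noisy click trains.

    One base train/test trial pair is shared across noise levels; only the
    mislocalization realization differs per level.
    """
    cfg = spec.task
    train = generate_trials(dataclasses.replace(cfg, seed=derive_seed(spec.seed, 0)),
                            spec.n_train)
    test = generate_trials(dataclasses.replace(cfg, seed=derive_seed(spec.seed, 1)),
                           spec.n_test, start_id=spec.n_train)
    rows = []
    for j, n in enumerate(spec.noise_levels):
        logger.info("noise study: level %g", n)
        kap = kappa(cfg.rate_high, cfg.rate_low, n)
        noisy_train = mislocalize_trials(train, n, derive_seed(spec.seed, 2, j))
        noisy_test = mislocalize_trials(test, n, derive_seed(spec.seed, 3, j))
        lam_star, _, _ = optimize_lambda(noisy_train)
        cmp_res = compare_linear_nonlinear(noisy_test, cfg.hazard_rate, kap,
                                           lam_star, seed=derive_seed(spec.seed, 4, j))
        rows.append({
            "n": n, "kappa": kap, "lam_star": lam_star,
            "acc_linear": cmp_res.acc_linear,
            "acc_nonlinear": cmp_res.acc_nonlinear,
            "agreement": cmp_res.agreement,
            "acc_ratio": cmp_res.accuracy_ratio,
        })
    df = pd.DataFrame(rows)
    _write_manifest(spec, _maybe_write(spec, df, f"{spec.name}_table"))
    return df


def run_timescale_recovery(spec: ExperimentSpec) -> pd.DataFrame:
    """Reverse-correlation recovery of the generative discounting rate.

    For each λ, a linear agent chooses on a fresh synthetic dataset
    (default 20k trials); the exponential fit to its end-aligned reverse
    correlation curve should recover b ≈ λ.
    """
    cfg = spec.task
    n_trials = spec.n_train if spec.n_train else 20_000
    trials = generate_trials(dataclasses.replace(cfg, seed=derive_seed(spec.seed, 10)),
                             n_trials)
    rows = []
    for j, lam in enumerate(spec.lambdas):
        logger.info("timescale recovery: lambda %g", lam)
        choices = decide_terminal(linear_terminal(trials, lam), trials,
                                  seed=derive_seed(spec.seed, 11, j))
        fit = recovery_fit(trials, choices, cfg.rate_high, cfg.rate_low,
                           seed=derive_seed(spec.seed, 12, j))
        rows.append({
            "lam": lam,
            "b_hat": fit.b,
            "b_ci_low": fit.b_ci[0],
            "b_ci_high": fit.b_ci[1],
            "a_hat": fit.a,
        })
    df = pd.DataFrame(rows)
    _write_manifest(spec, _maybe_write(spec, df, f"{spec.name}_recovery"))
    return df


def run_environment_switch(spec: ExperimentSpec,
                    segments: tuple[tuple[float, int], ...] = ((0.5, 3), (0.0, 3), (0.5, 3)),
                    subject_params: AccumulatorParams | None = None,
                    block_size: int = 7500,
                    n_optimize: int = 5000) -> pd.DataFrame:
    """Block-wise λ tracking of a synthetic subject across environment switches.

    ``segments`` lists (hazard rate, number of blocks).  The synthetic
    subject uses the numerically optimal linear discounting rate of each
    environment (floored at 0.2/s in static environments, matching the small
    but nonzero discounting of static-task subjects); its other accumulator
    parameters stay fixed and are also used, frozen, in the per-block λ fits.
    """
    if subject_params is None:
        subject_params = AccumulatorParams(sigma_a2=0.5, sigma_s2=2.0, sigma_i2=0.3,
                                           phi=0.9, tau_phi=0.06, bias=0.0, lapse=0.05)
    cfg = spec.task
    trials, lam_gen, seg_of_trial = [], [], []
    for si, (h, n_blocks) in enumerate(segments):
        env_cfg = dataclasses.replace(cfg, hazard_rate=h,
                                      seed=derive_seed(spec.seed, 20, si))
        opt_trials = generate_trials(env_cfg, n_optimize)
        lam_env, _, _ = optimize_lambda(opt_trials)
        lam_env = max(lam_env, 0.2)
        seg_trials = generate_trials(
            dataclasses.replace(env_cfg, seed=derive_seed(spec.seed, 21, si)),
            n_blocks * block_size, start_id=len(trials))
        logger.info("environment switch: segment %d h=%g lam=%.2f (%d trials)",
                    si, h, lam_env, len(seg_trials))
        trials.extend(seg_trials)
        lam_gen.extend([lam_env] * len(seg_trials))
        seg_of_trial.extend([si] * len(seg_trials))
    choices = np.empty(len(trials))
    # choices drawn segment-wise because the generative λ changes
    for si in range(len(segments)):
        idx = [i for i, s in enumerate(seg_of_trial) if s == si]
        params_si = dataclasses.replace(subject_params, lam=lam_gen[idx[0]])
        sub_choices = simulate_choices([trials[i] for i in idx], params_si,
                                       seed=derive_seed(spec.seed, 22, si))
        choices[idx] = sub_choices
    blocks = fit_lambda_blocks(trials, choices, subject_params, block_size)
    rows = []
    for blk in blocks:
        i0 = blk.block_index * block_size
        rows.append({
            "block": blk.block_index,
            "hazard": segments[seg_of_trial[i0]][0],
            "lam_generative": lam_gen[i0],
            "lam_hat": blk.lam,
            "ci_low": blk.ci[0], "ci_high": blk.ci[1],
            "n_trials": blk.n_trials,
        })
    df = pd.DataFrame(rows)
    _write_manifest(spec, _maybe_write(spec, df, f"{spec.name}_blocks"))
    return df
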