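"""Shared fixtures.

Heavy, multi-minute computations (the 30k-trial noise study and the
20k-trial model recovery) are session-scoped so every test that needs them
shares one run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import dynclicks as dc
from dynclicks.accumulator import AccumulatorParams, ChoiceData, fit, simulate_choices
from dynclicks.pipeline import derive_seed

MASTER_SEED = 1


@pytest.fixture(scope="session")
def study_config() -> dc.TaskConfig:
    """The study's task parameters: h = 1 Hz, rates ≈38.1/1.9 Hz (γ = 3)."""
    return dc.TaskConfig(seed=derive_seed(MASTER_SEED, 0))


@pytest.fixture(scope="session")
def small_trials(study_config) -> list[dc.Trial]:
    return dc.generate_trials(study_config, 300)


@dataclasses.dataclass
class NoiseStudy:
    """30k train / 30k test comparison of the two agents at average noise."""

    lam_star: float
    acc_linear: float
    acc_nonlinear: float
    agreement: float
    kappa: float
    n_test: int


@pytest.fixture(scope="session")
def noise_study(study_config) -> NoiseStudy:
    cfg = study_config
    n = 0.35
    train = dc.generate_trials(dataclasses.replace(cfg, seed=derive_seed(MASTER_SEED, 1)),
                               30_000)
    test = dc.generate_trials(dataclasses.replace(cfg, seed=derive_seed(MASTER_SEED, 2)),
                              30_000, start_id=30_000)
    noisy_train = dc.mislocalize_trials(train, n, derive_seed(MASTER_SEED, 3))
    noisy_test = dc.mislocalize_trials(test, n, derive_seed(MASTER_SEED, 4))
    lam_star, _, _ = dc.optimize_lambda(noisy_train)
    kap = dc.kappa(cfg.rate_high, cfg.rate_low, n)
    cmp_res = dc.compare_linear_nonlinear(noisy_test, cfg.hazard_rate, kap, lam_star,
                                          seed=derive_seed(MASTER_SEED, 5))
    return NoiseStudy(lam_star=lam_star, acc_linear=cmp_res.acc_linear,
                      acc_nonlinear=cmp_res.acc_nonlinear,
                      agreement=cmp_res.agreement, kappa=kap, n_test=len(test))


@dataclasses.dataclass
class RecoveryBundle:
    """20k-trial synthetic subject and its maximum-likelihood fit."""

    trials: list[dc.Trial]
    generative: AccumulatorParams
    choices: np.ndarray
    data: ChoiceData
    result: "dc.FitResult"


@pytest.fixture(scope="session")
def recovery_bundle(study_config) -> RecoveryBundle:
    cfg = dataclasses.replace(study_config, seed=derive_seed(MASTER_SEED, 10))
    trials = dc.generate_trials(cfg, 20_000)
    gen = AccumulatorParams(lam=8.0, sigma_a2=0.5, sigma_s2=2.0, sigma_i2=0.3,
                            phi=0.9, tau_phi=0.06, bias=0.0, lapse=0.05)
    choices = simulate_choices(trials, gen, seed=derive_seed(MASTER_SEED, 11))
    data = ChoiceData.from_trials(trials, choices)
    result = fit(data, n_starts=2, seed=derive_seed(MASTER_SEED, 12))
    return RecoveryBundle(trials=trials, generative=gen, choices=choices,
                          data=data, result=result)
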