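"""Trial-by-trial behavioral accumulator model.

The model describes choices as thresholded readout of a leaky, noisy
accumulator driven by the clicks:

    da = (δ_R·η_R·C − δ_L·η_L·C) dt − λa dt + σ_a dW
    dC/dt = (1 − C)/τ_ϕ + (ϕ − 1)·C·(δ_R + δ_L)

with multiplicative per-click sensory noise η ~ N(1, σ_s²), sensory
adaptation C (facilitation ϕ > 1, depression ϕ < 1, recovery time τ_ϕ),
accumulator diffusion σ_a², initial spread σ_i², a decision bias B and a
lapse rate.  Without absorbing bounds the accumulation distribution stays
Gaussian, with closed-form mean and variance at the end of the stimulus:

    μ(T)  = Σ_clicks ±C_i e^{−λ(T−t_i)}
    σ²(T) = σ_i² e^{−2λT} + σ_a²(1−e^{−2λT})/(2λ) + σ_s² Σ_clicks C_i e^{−2λ(T−t_i)}

(λ > 0 is a leak; the λ → 0 limit of the diffusion term is σ_a²·T).  Choice
probabilities follow from the Gaussian mass on either side of the bias B,
distorted by symmetric lapse.  Parameters are fit by penalized maximum
likelihood with half-Gaussian priors on σ_i and σ_a, and uncertainty comes
from the inverse Hessian at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import erf
from scipy.stats import qmc

from .task import RIGHT, Trial, trial_rng, _STREAM_CHOICE
from .agents import merged_clicks, state_signs

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("lam", "sigma_a2", "sigma_s2", "sigma_i2", "phi", "tau_phi",
                "bias", "lapse")

#: optimizer box constraints, in _PARAM_NAMES order
DEFAULT_BOUNDS = ((0.0, 40.0), (0.0, 50.0), (0.0, 50.0), (0.0, 50.0),
                  (1e-3, 5.0), (0.005, 1.0), (-5.0, 5.0), (0.0, 0.5))


@dataclass(frozen=True)
class AccumulatorParams:
    """The 8 model parameters (rates in 1/s, times in s, a in clicks units)."""

    lam: float = 0.0          # discounting (leak) rate; 1/lam = integration timescale
    sigma_a2: float = 0.0     # accumulator diffusion variance per second
    sigma_s2: float = 0.0     # per-click multiplicative sensory noise variance
    sigma_i2: float = 0.0     # variance of the initial accumulator value
    phi: float = 1.0          # adaptation strength (>1 facilitation, <1 depression)
    tau_phi: float = 0.1      # adaptation recovery time constant
    bias: float = 0.0         # decision threshold offset B
    lapse: float = 0.0        # probability of a stimulus-independent random choice

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_s2, self.sigma_i2) < 0:
            raise ValueError("variances must be nonnegative")
        if self.lam < 0:
            raise ValueError("discounting rate must be nonnegative")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must be in [0, 1]")
        if self.phi <= 0 or self.tau_phi <= 0:
            raise ValueError("phi and tau_phi must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_NAMES])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "AccumulatorParams":
        return cls(**dict(zip(_PARAM_NAMES, map(float, theta))))


@dataclass(frozen=True)
class PriorConfig:
    """Half-Gaussian prior scales on σ_i and σ_a (None disables a prior).

    The penalty added to the NLL is σ_i²/(2s_i²) + σ_a²/(2s_a²), the negative
    log of half-Gaussian densities on the noise standard deviations.
    """

    sigma_i_scale: float | None = 1.0
    sigma_a_scale: float | None = 1.0

    def penalty(self, params: AccumulatorParams) -> float:
        pen = 0.0
        if self.sigma_i_scale is not None:
            pen += params.sigma_i2 / (2.0 * self.sigma_i_scale ** 2)
        if self.sigma_a_scale is not None:
            pen += params.sigma_a2 / (2.0 * self.sigma_a_scale ** 2)
        return pen


NO_PRIORS = PriorConfig(sigma_i_scale=None, sigma_a_scale=None)


# ---------------------------------------------------------------------------
# adaptation and closed-form moments
# ---------------------------------------------------------------------------

def adaptation_trace(click_times: np.ndarray, phi: float, tau_phi: float) -> np.ndarray:
    """Adaptation value C applied to each click of a merged, sorted train.

    C starts at 1, relaxes toward 1 between clicks with time constant τ_ϕ,
    and is multiplied by ϕ immediately *after* each click; the value used to
    weight a click is the pre-multiplication one.
    """
    if phi <= 0 or tau_phi <= 0:
        raise ValueError("phi and tau_phi must be positive")
    click_times = np.asarray(click_times, dtype=float)
    weights = np.empty(click_times.size)
    c_state = 1.0  # value just after the previous click's multiplication
    prev = 0.0
    for i, t in enumerate(click_times):
        c_pre = 1.0 + (c_state - 1.0) * np.exp(-(t - prev) / tau_phi)
        weights[i] = c_pre
        c_state = phi * c_pre
        prev = t
    return weights


@dataclass
class TrialMoments:
    """Gaussian accumulation distribution at decision time."""

    mu: float
    var: float
    adaptation: np.ndarray  # C at each merged click


def _diffusion_factor(lam: float, T) -> np.ndarray:
    """(1 − e^{−2λT})/(2λ), with its λ→0 limit T."""
    T = np.asarray(T, dtype=float)
    if lam < 1e-12:
        return T
    return -np.expm1(-2.0 * lam * T) / (2.0 * lam)


def trial_moments(trial: Trial, params: AccumulatorParams) -> TrialMoments:
    """Closed-form mean and variance of the accumulator at stimulus end."""
    ct, cs = merged_clicks(trial)
    C = adaptation_trace(ct, params.phi, params.tau_phi)
    decay = np.exp(-params.lam * (trial.duration - ct))
    mu = float(np.sum(cs * C * decay))
    var = (params.sigma_i2 * np.exp(-2.0 * params.lam * trial.duration)
           + params.sigma_a2 * float(_diffusion_factor(params.lam, trial.duration))
           + params.sigma_s2 * float(np.sum(C * decay ** 2)))
    return TrialMoments(mu=mu, var=var, adaptation=C)


def choice_probability(mu, var, params: AccumulatorParams):
    """P(go right), P(go left) including the lapse distortion.

    Base probability is the Gaussian mass above the bias B,
    ½(1 + erf((μ − B)/(σ√2))); at σ = 0 a step function (½ exactly at B).
    Lapse mixes in uniform guessing: P' = lapse/2 + (1 − lapse)·P.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be nonnegative")
    z = mu - params.bias
    with np.errstate(divide="ignore", invalid="ignore"):
        base = 0.5 * (1.0 + erf(z / np.sqrt(2.0 * var)))
    base = np.where(var == 0, np.where(z > 0, 1.0, np.where(z < 0, 0.0, 0.5)), base)
    p_right = params.lapse / 2.0 + (1.0 - params.lapse) * base
    if p_right.ndim == 0:
        return float(p_right), float(1.0 - p_right)
    return p_right, 1.0 - p_right


# ---------------------------------------------------------------------------
# padded-array dataset representation (vectorized likelihood)
# ---------------------------------------------------------------------------

@dataclass
class ChoiceData:
    """A choice dataset flattened to padded arrays for fast likelihood evaluation."""

    times: np.ndarray      # (n_trials, k_max) merged click times, padded
    signs: np.ndarray      # (n_trials, k_max) ±1, 0 on padding
    gaps: np.ndarray       # (n_trials, k_max) inter-click gaps (0 on padding)
    mask: np.ndarray       # (n_trials, k_max) True on real clicks
    T: np.ndarray          # (n_trials,) durations
    choice: np.ndarray     # (n_trials,) +1 right / −1 left
    truth: np.ndarray      # (n_trials,) terminal hidden state sign

    @property
    def n_trials(self) -> int:
        return self.T.size

    @classmethod
    def from_trials(cls, trials: list[Trial], choices: np.ndarray | None = None
                    ) -> "ChoiceData":
        if choices is None:
            if any(t.choice is None for t in trials):
                raise ValueError("every trial needs a recorded choice")
            choices = np.array([1.0 if t.choice == RIGHT else -1.0 for t in trials])
        choices = np.asarray(choices, dtype=float)
        n = len(trials)
        k_max = max((t.right_clicks.size + t.left_clicks.size for t in trials),
                    default=0)
        times = np.zeros((n, k_max))
        signs = np.zeros((n, k_max))
        mask = np.zeros((n, k_max), dtype=bool)
        T = np.array([t.duration for t in trials])
        for i, trial in enumerate(trials):
            ct, cs = merged_clicks(trial)
            times[i, :ct.size] = ct
            times[i, ct.size:] = trial.duration
            signs[i, :cs.size] = cs
            mask[i, :ct.size] = True
        gaps = np.diff(times, axis=1, prepend=0.0)
        return cls(times=times, signs=signs, gaps=gaps, mask=mask, T=T,
                   choice=choices, truth=state_signs(trials))


def _adaptation_padded(data: ChoiceData, phi: float, tau_phi: float) -> np.ndarray:
    """Vectorized adaptation weights over a padded dataset."""
    relax = np.exp(-data.gaps / tau_phi)
    n, k_max = data.times.shape
    C = np.empty((n, k_max))
    c_state = np.ones(n)
    for k in range(k_max):
        c_pre = 1.0 + (c_state - 1.0) * relax[:, k]
        C[:, k] = c_pre
        c_state = phi * c_pre
    return C


def dataset_moments(data: ChoiceData, params: AccumulatorParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(μ, σ²) at decision time for every trial of a padded dataset."""
    C = _adaptation_padded(data, params.phi, params.tau_phi)
    decay = np.exp(-params.lam * (data.T[:, None] - data.times))
    Cm = np.where(data.mask, C, 0.0)
    mu = np.sum(data.signs * Cm * decay, axis=1)
    var = (params.sigma_i2 * np.exp(-2.0 * params.lam * data.T)
           + params.sigma_a2 * _diffusion_factor(params.lam, data.T)
           + params.sigma_s2 * np.sum(Cm * decay ** 2, axis=1))
    return mu, var


def predicted_p_right(data: ChoiceData, params: AccumulatorParams) -> np.ndarray:
    mu, var = dataset_moments(data, params)
    p_right, _ = choice_probability(mu, var, params)
    return p_right


def negative_log_likelihood(data: ChoiceData, params: AccumulatorParams,
                            prior: PriorConfig = PriorConfig()) -> float:
    """Penalized NLL of the recorded choices.

    Returns +inf (not an exception) if any choice has probability zero,
    which can only happen at lapse = 0 with a degenerate (σ = 0) trial.
    """
    p_right = predicted_p_right(data, params)
    p_choice = np.where(data.choice > 0, p_right, 1.0 - p_right)
    if np.any(p_choice <= 0.0):
        return float("inf")
    return float(-np.sum(np.log(p_choice)) + prior.penalty(params))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: AccumulatorParams
    nll: float
    hessian: np.ndarray
    covariance: np.ndarray
    ci: dict[str, tuple[float, float]]
    pseudo_inverse: bool
    eigenvalues: np.ndarray = field(default=None)
    eigenvectors: np.ndarray = field(default=None)
    param_names: tuple[str, ...] = _PARAM_NAMES


_THETA_FLOOR = np.array([0.0, 0.0, 0.0, 0.0, 1e-6, 1e-6, -np.inf, 0.0])
_THETA_CEIL = np.array([np.inf, np.inf, np.inf, np.inf, np.inf, np.inf, np.inf, 1.0])

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _diffusion_factor_grad(lam: float, T: np.ndarray) -> np.ndarray:
    """d/dλ of (1 − e^{−2λT})/(2λ), with its λ→0 limit −T²."""
    if lam < 1e-6:
        return -T ** 2
    e = np.exp(-2.0 * lam * T)
    return T * e / lam - (1.0 - e) / (2.0 * lam ** 2)


def nll_and_grad(data: ChoiceData, theta: np.ndarray,
                 prior: PriorConfig = PriorConfig()) -> tuple[float, np.ndarray]:
    """Penalized NLL and its exact gradient at a raw parameter vector.

    The gradient chains analytically through the Gaussian moments and the
    adaptation recursion (dC/dϕ and dC/dτ_ϕ propagate through the same
    linear recursion as C itself), so one call costs only a small multiple
    of a plain NLL evaluation.  ``theta`` is clipped to the model domain but
    not validated, which lets optimizers probe freely within bounds.
    """
    theta = np.clip(theta, _THETA_FLOOR, _THETA_CEIL)
    lam, sa2, ss2, si2, phi, tau, B, lapse = theta
    # adaptation and its parameter sensitivities
    relax = np.exp(-data.gaps / tau)
    drelax_dtau = relax * data.gaps / tau ** 2
    n, k_max = data.times.shape
    C = np.empty((n, k_max))
    dC_dphi = np.empty((n, k_max))
    dC_dtau = np.empty((n, k_max))
    c_state = np.ones(n)
    dstate_dphi = np.zeros(n)
    dstate_dtau = np.zeros(n)
    for k in range(k_max):
        r = relax[:, k]
        c_pre = 1.0 + (c_state - 1.0) * r
        dpre_dphi = dstate_dphi * r
        dpre_dtau = dstate_dtau * r + (c_state - 1.0) * drelax_dtau[:, k]
        C[:, k] = c_pre
        dC_dphi[:, k] = dpre_dphi
        dC_dtau[:, k] = dpre_dtau
        c_state = phi * c_pre
        dstate_dphi = c_pre + phi * dpre_dphi
        dstate_dtau = phi * dpre_dtau
    lag = data.T[:, None] - data.times
    E = np.exp(-lam * lag)
    E2 = E * E
    m = data.mask
    sCE = np.where(m, data.signs * C, 0.0) * E
    mu = np.sum(sCE, axis=1)
    dmu_dlam = -np.sum(sCE * lag, axis=1)
    dmu_dphi = np.sum(np.where(m, data.signs * dC_dphi, 0.0) * E, axis=1)
    dmu_dtau = np.sum(np.where(m, data.signs * dC_dtau, 0.0) * E, axis=1)
    CE2 = np.where(m, C, 0.0) * E2
    sum_CE2 = np.sum(CE2, axis=1)
    e2T = np.exp(-2.0 * lam * data.T)
    g = _diffusion_factor(lam, data.T)
    V = si2 * e2T + sa2 * g + ss2 * sum_CE2
    V = np.maximum(V, 1e-12)
    dV_dlam = (si2 * (-2.0 * data.T) * e2T + sa2 * _diffusion_factor_grad(lam, data.T)
               + ss2 * np.sum(CE2 * (-2.0 * lag), axis=1))
    dV_dphi = ss2 * np.sum(np.where(m, dC_dphi, 0.0) * E2, axis=1)
    dV_dtau = ss2 * np.sum(np.where(m, dC_dtau, 0.0) * E2, axis=1)
    # choice probability p = lapse/2 + (1−lapse)Φ(y·z), z = (μ−B)/σ
    sigma = np.sqrt(V)
    z = (mu - B) / sigma
    y = data.choice
    yz = y * z
    Phi = 0.5 * (1.0 + erf(yz / np.sqrt(2.0)))
    p = lapse / 2.0 + (1.0 - lapse) * Phi
    p = np.maximum(p, 1e-300)
    nll = float(-np.sum(np.log(p)))
    # chain rule: dNLL/dq = −Σ (1/p)·(1−lapse)·y·pdf(z)·dz/dq  (+ lapse term)
    pdf = np.exp(-0.5 * z * z) / _SQRT2PI
    w = (1.0 - lapse) * y * pdf / p
    dz_dmu = 1.0 / sigma
    dz_dV = -0.5 * (mu - B) / (V * sigma)
    grad = np.empty(8)
    grad[0] = -np.sum(w * (dz_dmu * dmu_dlam + dz_dV * dV_dlam))
    grad[1] = -np.sum(w * dz_dV * g)             # σa²
    grad[2] = -np.sum(w * dz_dV * sum_CE2)       # σs²
    grad[3] = -np.sum(w * dz_dV * e2T)           # σi²
    grad[4] = -np.sum(w * (dz_dmu * dmu_dphi + dz_dV * dV_dphi))
    grad[5] = -np.sum(w * (dz_dmu * dmu_dtau + dz_dV * dV_dtau))
    grad[6] = -np.sum(w * (-dz_dmu))             # bias
    grad[7] = -np.sum((0.5 - Phi) / p)           # lapse
    if prior.sigma_i_scale is not None:
        nll += si2 / (2.0 * prior.sigma_i_scale ** 2)
        grad[3] += 1.0 / (2.0 * prior.sigma_i_scale ** 2)
    if prior.sigma_a_scale is not None:
        nll += sa2 / (2.0 * prior.sigma_a_scale ** 2)
        grad[1] += 1.0 / (2.0 * prior.sigma_a_scale ** 2)
    return nll, grad


def _objective(data: ChoiceData, prior: PriorConfig):
    def fun(theta: np.ndarray) -> float:
        return nll_and_grad(data, theta, prior)[0]
    return fun


def finite_difference_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4,
                              abs_floor: float = 1e-6) -> np.ndarray:
    """Central-difference Hessian with per-parameter relative steps."""
    p = theta.size
    steps = np.maximum(np.abs(theta) * rel_step, abs_floor)
    H = np.empty((p, p))
    f0 = fun(theta)
    for i in range(p):
        ei = np.zeros(p); ei[i] = steps[i]
        H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H


def _covariance(H: np.ndarray) -> tuple[np.ndarray, bool]:
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        return cov, False
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H, hermitian=True), True


def fit(data: ChoiceData, init: AccumulatorParams | None = None,
        bounds=DEFAULT_BOUNDS, prior: PriorConfig = PriorConfig(),
        n_starts: int = 8, seed: int = 0) -> FitResult:
    """Penalized maximum-likelihood fit of all 8 parameters.

    Bounded quasi-Newton (L-BFGS-B) from ``n_starts`` Latin-hypercube starts
    (plus ``init`` if given); the best converged optimum wins.  Covariance
    and 95% CIs come from the inverse finite-difference Hessian at the
    optimum (pseudo-inverse, flagged, when near-singular); the Hessian
    eigen-decomposition is exposed for parameter trade-off analysis.
    """
    fun = _objective(data, prior)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = []
    if init is not None:
        starts.append(init.to_array())
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    span_hi = np.minimum(hi, np.array([20.0, 5.0, 5.0, 5.0, 2.0, 0.5, 1.0, 0.3]))
    for row in sampler.random(n_starts):
        starts.append(lo + row * (span_hi - lo))
    best = None
    for k, x0 in enumerate(starts):
        res = minimize(lambda th: nll_and_grad(data, th, prior), x0,
                       method="L-BFGS-B", jac=True, bounds=bounds,
                       options={"maxiter": 500})
        logger.debug("start %d: nll=%.3f success=%s", k, res.fun, res.success)
        if res.success or np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("optimizer failed to converge from every start")
    theta = best.x
    H = finite_difference_hessian(fun, theta)
    cov, pinv_used = _covariance(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ci = {name: (float(theta[i] - 1.96 * se[i]), float(theta[i] + 1.96 * se[i]))
          for i, name in enumerate(_PARAM_NAMES)}
    eigvals, eigvecs = np.linalg.eigh(0.5 * (H + H.T))
    return FitResult(
        params=AccumulatorParams.from_array(theta),
        nll=float(best.fun),
        hessian=H, covariance=cov, ci=ci, pseudo_inverse=pinv_used,
        eigenvalues=eigvals, eigenvectors=eigvecs,
    )


# ---------------------------------------------------------------------------
# synthetic choices, noise back-out, optimality analyses
# ---------------------------------------------------------------------------

def simulate_choices(trials: list[Trial], params: AccumulatorParams,
                     seed: int = 0) -> np.ndarray:
    """Sample one choice per trial (+1/−1) from the model's own probabilities.

    Per-trial random substreams keyed on (seed, trial_id), so the draw for a
    trial is independent of dataset order.
    """
    data = ChoiceData.from_trials(trials, np.ones(len(trials)))
    p_right = predicted_p_right(data, params)
    out = np.empty(len(trials))
    for i, trial in enumerate(trials):
        rng = trial_rng(seed, trial.trial_id, _STREAM_CHOICE)
        out[i] = 1.0 if rng.random() < p_right[i] else -1.0
    return out


def noise_level(params: AccumulatorParams, reference_trials: list[Trial]) -> float:
    """Effective click mislocalization probability implied by the model.

    A click's registered weight is η·C with η ~ N(1, σ_s²); the probability
    that the weight crosses zero (the click is heard on the wrong side) at
    the dataset-average adaptation ⟨C⟩ is
    n = ½(1 + erf(−⟨C⟩ / √(2 σ_s² ⟨C⟩))).
    """
    if params.sigma_s2 == 0:
        return 0.0
    weights = [adaptation_trace(merged_clicks(t)[0], params.phi, params.tau_phi)
               for t in reference_trials]
    mean_c = float(np.mean(np.concatenate(weights)))
    return float(0.5 * (1.0 + erf(-mean_c / np.sqrt(2.0 * params.sigma_s2 * mean_c))))


def expected_accuracy(data: ChoiceData, params: AccumulatorParams) -> float:
    """Model-expected fraction of correct terminal-state reports."""
    p_right = predicted_p_right(data, params)
    p_correct = np.where(data.truth > 0, p_right, 1.0 - p_right)
    return float(np.mean(p_correct))


def accuracy_maximizing_lambda(params: AccumulatorParams, trials: list[Trial],
                               lambda_grid: np.ndarray | None = None
                               ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Accuracy-optimal discounting rate with all other parameters frozen.

    Returns (λ_acc, grid, expected-accuracy curve, accuracy gain over the
    fitted λ).  Expected accuracy is computed from the model's own choice
    probabilities against the true terminal states.
    """
    data = ChoiceData.from_trials(trials, np.ones(len(trials)))
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 40.0 + 1e-9, 0.5)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    def acc(lam: float) -> float:
        return expected_accuracy(data, replace(params, lam=float(lam)))

    curve = np.array([acc(lam) for lam in lambda_grid])
    best = int(np.argmax(curve))
    lam_acc = float(lambda_grid[best])
    lo = max(lambda_grid[0], lam_acc - 0.5)
    hi = min(lambda_grid[-1], lam_acc + 0.5)
    res = minimize_scalar(lambda lam: -acc(lam), bounds=(lo, hi), method="bounded")
    if -res.fun >= curve[best]:
        lam_acc = float(res.x)
    gain = acc(lam_acc) - acc(params.lam)
    return lam_acc, lambda_grid, curve, gain


@dataclass
class BlockFit:
    block_index: int
    n_trials: int
    lam: float
    ci: tuple[float, float]
    nll: float


def fit_lambda_blocks(trials: list[Trial], choices: np.ndarray,
                      frozen: AccumulatorParams, block_size: int = 7500,
                      lam_bounds: tuple[float, float] = (0.0, 40.0)) -> list[BlockFit]:
    """1-D ML fit of λ on consecutive chronological blocks of trials.

    All other parameters stay at ``frozen``.  A trailing partial block
    shorter than 20% of ``block_size`` is dropped with a logged warning.
    CIs are ±1.96/√(d²NLL/dλ²) from a central difference at the optimum.
    """
    choices = np.asarray(choices, dtype=float)
    results: list[BlockFit] = []
    n = len(trials)
    starts = list(range(0, n, block_size))
    for b, s in enumerate(starts):
        sub = trials[s:s + block_size]
        if len(sub) < 0.2 * block_size:
            logger.warning("dropping final partial block of %d trials (< 20%% of %d)",
                           len(sub), block_size)
            continue
        data = ChoiceData.from_trials(sub, choices[s:s + block_size])

        def nll_lam(lam: float) -> float:
            return negative_log_likelihood(data, replace(frozen, lam=float(lam)),
                                           prior=NO_PRIORS)

        # profile NLL can have a shallow secondary dip at very large λ, so
        # scan a coarse grid first and refine only around the global basin
        grid = np.arange(lam_bounds[0], lam_bounds[1] + 1e-9, 0.5)
        coarse = np.array([nll_lam(lam) for lam in grid])
        gbest = int(np.argmin(coarse))
        lo = grid[max(gbest - 1, 0)]
        hi = grid[min(gbest + 1, grid.size - 1)]
        res = minimize_scalar(nll_lam, bounds=(lo, hi), method="bounded")
        lam_hat = float(res.x)
        step = max(1e-3, 1e-3 * lam_hat)
        if lam_hat - step >= lam_bounds[0]:
            d2 = (nll_lam(lam_hat + step) - 2.0 * res.fun
                  + nll_lam(lam_hat - step)) / step ** 2
        else:  # optimum at the lower bound: one-sided curvature
            d2 = (nll_lam(lam_hat + 2 * step) - 2.0 * nll_lam(lam_hat + step)
                  + res.fun) / step ** 2
        se = 1.0 / np.sqrt(d2) if d2 > 0 else np.inf
        results.append(BlockFit(block_index=b, n_trials=len(sub), lam=lam_hat,
                                ci=(lam_hat - 1.96 * se, lam_hat + 1.96 * se),
                                nll=float(res.fun)))
    return results
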