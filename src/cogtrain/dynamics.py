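"""Cognitive-state models and plasticity rules.

Session-resolution dynamics of the simulated trainee:

* executive function (EF) as a weighted sum of working memory, inhibitory
  control and cognitive flexibility plus Gaussian noise;
* tactical cognition (TC) as a lagged weighted sum of situational
  awareness, pattern recognition, decision-making and strategic planning;
* a performance composite with a multiplicative EF x TC synergy term;
* session-to-session update rules for EF (component deltas plus a
  neurofeedback term) and TC (component deltas plus context and
  cross-domain transfer terms), clamped to the 0-100 score scale;
* the Bienenstock-Cooper-Munro (BCM) synaptic plasticity rule, a
  spike-timing-weighted synaptic modification index, a training-adaptation
  function with exponential decay of the neurofeedback drive, and a
  normalised cognitive performance index.

Greek-letter parameters are namespaced per equation (each rule has its own
dataclass), since the same symbols recur with different meanings across
rules.  Time is discrete at session resolution and all component lags are
integer session lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

logger = logging.getLogger(__name__)

__all__ = [
    "CognitiveState", "EFModelParams", "TCModelParams", "PerformanceParams",
    "UpdateParams", "PlasticityParams", "AdaptationParams", "CPIWeights",
    "clamp_score", "ef_score", "tc_score", "performance_score", "ef_step",
    "tc_step", "bcm_delta", "training_adaptation", "smi", "cpi",
]


def clamp_score(value: float, label: str = "score") -> float:
    """Clamp to the [0, 100] score scale; clamping is logged."""
    clamped = min(max(value, 0.0), 100.0)
    if clamped != value:
        logger.info("clamped %s from %.3f to %.1f", label, value, clamped)
    return clamped


@dataclass
class CognitiveState:
    """Component scores and composites at one session index t."""

    wm: float = 0.0
    ic: float = 0.0
    cf: float = 0.0
    sa: float = 0.0
    pr: float = 0.0
    dm: float = 0.0
    sp: float = 0.0
    ef: float = 0.0
    tc: float = 0.0
    performance: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("session index t must be >= 0")


@dataclass
class EFModelParams:
    """EF composite weights (alpha1..3) and noise SD in score units."""

    alpha1: float = 1 / 3
    alpha2: float = 1 / 3
    alpha3: float = 1 / 3
    noise_sd: float = 0.0


@dataclass
class TCModelParams:
    """TC composite weights (beta1..4) and integer session lags."""

    beta1: float = 0.25
    beta2: float = 0.25
    beta3: float = 0.25
    beta4: float = 0.25
    delay1: int = 0
    delay2: int = 0
    delay3: int = 0
    delay4: int = 0

    def __post_init__(self) -> None:
        for d in (self.delay1, self.delay2, self.delay3, self.delay4):
            if d < 0 or int(d) != d:
                raise ValueError("lags must be integers >= 0")


@dataclass
class PerformanceParams:
    """Performance composite: gamma1 (EF x TC synergy), gamma2 (EF),
    gamma3 (TC), and noise SD."""

    gamma1: float = 0.0
    gamma2: float = 0.5
    gamma3: float = 0.5
    noise_sd: float = 0.0


@dataclass
class UpdateParams:
    """Session-update coefficients: rho1..3 EF learning rates, lambda_fb
    neurofeedback coefficient, mu per-TC-component rates, phi_context and
    psi_transfer coupling coefficients."""

    rho1: float = 1.0
    rho2: float = 1.0
    rho3: float = 1.0
    lambda_fb: float = 0.0
    mu: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    phi_context: float = 0.0
    psi_transfer: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rho1, self.rho2, self.rho3) < 0 or min(self.mu) < 0:
            raise ValueError("learning rates must be >= 0")


@dataclass
class PlasticityParams:
    """BCM / STDP parameters: eta learning rate, theta_j plasticity
    threshold, w0 initial weight, stdp_tau kernel time constant (s)."""

    eta: float = 0.1
    theta_j: float = 1.0
    w0: float = 1.0
    stdp_tau: float = 0.02

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class AdaptationParams:
    """Training-adaptation function: lambda_ta plasticity coefficient,
    delta_ta decay constant (>= 0), beta_practice weight, nf0 baseline
    neurofeedback value."""

    lambda_ta: float = 1.0
    delta_ta: float = 0.1
    beta_practice: float = 0.0
    nf0: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_ta < 0:
            raise ValueError("delta_ta must be >= 0")


@dataclass
class CPIWeights:
    """Per-domain weights (>= 0, not all zero) and normalisation
    constants for the cognitive performance index."""

    weights: dict[str, float]
    norm_ref: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if sum(self.weights.values()) <= 0:
            raise ValueError("weights must not all be zero")


def ef_score(state: CognitiveState, p: EFModelParams,
             noise_seed: int | None = None) -> float:
    """EF(t) = a1*WM + a2*IC + a3*CF + eps, eps ~ N(0, noise_sd^2)."""
    eps = 0.0
    if p.noise_sd > 0:
        eps = float(np.random.default_rng(noise_seed).normal(0, p.noise_sd))
    return p.alpha1 * state.wm + p.alpha2 * state.ic + p.alpha3 * state.cf + eps


def tc_score(history: list[CognitiveState], p: TCModelParams) -> float:
    """TC(t) = b1*SA(t-d1) + b2*PR(t-d2) + b3*DM(t-d3) + b4*SP(t-d4),
    evaluated at the last state of ``history`` with integer session lags."""
    max_lag = max(p.delay1, p.delay2, p.delay3, p.delay4)
    if len(history) <= max_lag:
        raise ValueError(f"history length {len(history)} insufficient for "
                         f"max lag {max_lag}")
    t = len(history) - 1
    return (p.beta1 * history[t - p.delay1].sa
            + p.beta2 * history[t - p.delay2].pr
            + p.beta3 * history[t - p.delay3].dm
            + p.beta4 * history[t - p.delay4].sp)


def performance_score(ef: float, tc: float, p: PerformanceParams,
                      noise_seed: int | None = None) -> float:
    """Performance = g1*EF*TC + g2*EF + g3*TC + eta."""
    if not (np.isfinite(ef) and np.isfinite(tc)):
        raise ValueError("ef and tc must be finite")
    eta = 0.0
    if p.noise_sd > 0:
        eta = float(np.random.default_rng(noise_seed).normal(0, p.noise_sd))
    return p.gamma1 * ef * tc + p.gamma2 * ef + p.gamma3 * tc + eta


def ef_step(ef: float, deltas: tuple[float, float, float], feedback: float,
            p: UpdateParams) -> float:
    """EF(t+1) = EF + rho1*dWM + rho2*dIC + rho3*dCF + lambda*FB,
    clamped to [0, 100]."""
    nxt = (ef + p.rho1 * deltas[0] + p.rho2 * deltas[1]
           + p.rho3 * deltas[2] + p.lambda_fb * feedback)
    return clamp_score(nxt, "EF")


def tc_step(tc: float, component_deltas: tuple[float, ...], context: float,
            transfer: float, p: UpdateParams) -> float:
    """TC(t+1) = TC + sum_i mu_i*dTC_i + phi*Context + psi*Transfer,
    clamped to [0, 100]."""
    if len(component_deltas) > len(p.mu):
        raise ValueError("more component deltas than mu rates")
    nxt = tc + sum(m * d for m, d in zip(p.mu, component_deltas))
    nxt += p.phi_context * context + p.psi_transfer * transfer
    return clamp_score(nxt, "TC")


def bcm_delta(x_pre: float, y_post: float, p: PlasticityParams) -> float:
    """BCM weight change: eta * y * (y - theta) * x.  Negative (synaptic
    depression) for 0 < y < theta, positive (potentiation) for y > theta."""
    return p.eta * y_post * (y_post - p.theta_j) * x_pre


def training_adaptation(nf_t: float, t: float, practice_t: float,
                        p: AdaptationParams) -> float:
    """TA(t) = lambda*(NF(t) - NF0)*exp(-delta*t) + beta*Practice(t).

    The neurofeedback drive decays exponentially with the delta_ta decay
    constant; practice contributes without decay.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return (p.lambda_ta * (nf_t - p.nf0) * np.exp(-p.delta_ta * t)
            + p.beta_practice * practice_t)


def smi(pre_rate_fn, post_rate_fn, window: tuple[float, float],
        p: PlasticityParams, delta_t: float = 0.0) -> float:
    """Synaptic modification index dw/w0 with
    dw = eta * integral f(pre)(t) * f(post)(t) * g(delta_t) dt,
    where g is an exponential spike-timing kernel
    g(dt) = exp(-|dt| / stdp_tau), evaluated by numerical quadrature
    over ``window``."""
    if p.w0 <= 0:
        raise ValueError("w0 must be > 0")
    g = float(np.exp(-abs(delta_t) / p.stdp_tau))

    def integrand(t: float) -> float:
        return pre_rate_fn(t) * post_rate_fn(t) * g

    val, _ = quad(integrand, window[0], window[1], limit=200)
    return p.eta * val / p.w0


def cpi(domain_scores: dict[str, float], w: CPIWeights) -> float:
    """Cognitive performance index: weighted mean of normalised domain
    scores, sum_i w_i*(C_i/norm_i) / sum_i w_i (norm defaults to 100)."""
    total_w = sum(w.weights.values())
    acc = 0.0
    for domain, weight in w.weights.items():
        if domain not in domain_scores:
            raise ValueError(f"missing domain score: {domain}")
        norm = w.norm_ref.get(domain, 100.0)
        acc += weight * domain_scores[domain] / norm
    return acc / total_w
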