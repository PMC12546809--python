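"""Multimodal feature fusion.

Two fusion rules: a linear-plus-interaction combination of time-aligned
modality streams (weighted sum plus pairwise product terms over unordered
modality pairs), and a scalar Kalman filter that treats each modality as a
noisy observation of one shared latent state, reporting per-step,
per-modality gains.  Gains are independent scalars per modality applied
through sequential measurement updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FusionWeights", "KalmanConfig", "KalmanResult", "linear_fuse",
           "kalman_fuse"]


@dataclass
class FusionWeights:
    """Linear weight per modality and cross weight per unordered pair.

    Cross keys are (modality_a, modality_b) tuples; order is ignored.
    """

    linear: dict[str, float]
    cross: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.linear.values():
            if not np.isfinite(w):
                raise ValueError("linear weights must be finite")
        norm: dict[tuple[str, str], float] = {}
        for (a, b), w in self.cross.items():
            if not np.isfinite(w):
                raise ValueError("cross weights must be finite")
            if a not in self.linear or b not in self.linear:
                raise ValueError(f"cross pair ({a}, {b}) references a "
                                 "modality without a linear weight")
            norm[tuple(sorted((a, b)))] = w
        self.cross = norm


@dataclass
class KalmanConfig:
    """Scalar-state filter configuration: process noise variance,
    per-modality observation noise variances, initial state and
    variance."""

    process_noise: float
    obs_noise: dict[str, float]
    init_state: float = 0.0
    init_var: float = 1.0

    def __post_init__(self) -> None:
        if self.process_noise < 0:
            raise ValueError("process_noise must be >= 0")
        if any(v < 0 for v in self.obs_noise.values()):
            raise ValueError("obs_noise variances must be >= 0")
        if self.init_var <= 0:
            raise ValueError("init_var must be > 0")


@dataclass
class KalmanResult:
    """Fused state trajectory with per-step diagnostics."""

    state: np.ndarray
    variance: np.ndarray
    gains: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"state": self.state, "variance": self.variance})
        for m, g in self.gains.items():
            df[f"gain_{m}"] = g
        return df


def linear_fuse(streams: dict[str, np.ndarray],
                weights: FusionWeights) -> np.ndarray:
    """Elementwise S = sum_i w_i S_i + sum_{j<k} w_jk S_j S_k over
    time-aligned, equal-length modality streams."""
    unknown = set(weights.linear) - set(streams)
    if unknown:
        raise ValueError(f"weights reference unknown modalities: {unknown}")
    arrays = {m: np.asarray(s, dtype=float) for m, s in streams.items()}
    lengths = {m: a.shape[-1] for m, a in arrays.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"stream length mismatch: {lengths}")
    n = next(iter(lengths.values()))
    out = np.zeros(n)
    for m, w in weights.linear.items():
        out += w * arrays[m]
    for (a, b), w in weights.cross.items():
        out += w * arrays[a] * arrays[b]
    return out


def kalman_fuse(observations: dict[str, np.ndarray],
                cfg: KalmanConfig) -> KalmanResult:
    """Fuse per-modality observation series into one latent-state series.

    Standard scalar predict/update recursion; each modality is applied as
    a sequential measurement update with its own noise variance, producing
    a gain in [0, 1] per modality per step.  A zero-noise modality pins
    the state to its observation; conflicting zero-noise observations are
    flagged.
    """
    if not observations:
        raise ValueError("at least one modality required")
    modalities = list(observations)
    missing = set(modalities) - set(cfg.obs_noise)
    if missing:
        raise ValueError(f"obs_noise missing for modalities: {missing}")
    obs = {m: np.asarray(z, dtype=float) for m, z in observations.items()}
    lengths = {m: z.size for m, z in obs.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"observation length mismatch: {lengths}")
    n = next(iter(lengths.values()))

    zero_noise = [m for m in modalities if cfg.obs_noise[m] == 0.0]
    if len(zero_noise) > 1:
        z0 = np.array([obs[m] for m in zero_noise])
        if not np.allclose(z0, z0[0]):
            logger.warning("kalman_fuse: multiple zero-noise modalities "
                           "with conflicting observations; later updates "
                           "override earlier ones")

    x, p = cfg.init_state, cfg.init_var
    state = np.empty(n)
    variance = np.empty(n)
    gains = {m: np.empty(n) for m in modalities}
    for t in range(n):
        p = p + cfg.process_noise
        for m in modalities:
            r = cfg.obs_noise[m]
            k = p / (p + r) if (p + r) > 0 else 0.0
            x = x + k * (obs[m][t] - x)
            p = (1.0 - k) * p
            gains[m][t] = k
        state[t] = x
        variance[t] = p
    return KalmanResult(state=state, variance=variance, gains=gains)
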