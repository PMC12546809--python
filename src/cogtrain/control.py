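"""Closed-loop adaptive control.

Task difficulty adapts toward a target performance level with a neural-load
correction and is clamped to the level range of its task type; feedback
actions are chosen by finite-horizon discounted-return planning over a
small discrete decision process; convergence of the closed loop is checked
against an exponential Lyapunov envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TaskSpec", "DifficultyParams", "FeedbackPolicy",
           "StabilityCriterion", "TASK_LEVELS", "TASK_DURATIONS_MIN",
           "difficulty_step", "select_feedback", "lyapunov_check",
           "DEFAULT_FEEDBACK_ACTIONS"]

#: Difficulty-level range per training task type.
TASK_LEVELS: dict[str, tuple[int, int]] = {
    "working_memory_update": (1, 5),      # item quantity
    "inhibitory_control": (1, 4),         # conflict intensity
    "cognitive_flexibility": (1, 3),      # switch frequency
    "tactical_recognition": (1, 6),       # complexity level
    "strategic_planning": (1, 4),         # planning depth
    "integrated_scenarios": (1, 5),       # scenario complexity
}

#: Session duration range (minutes) per task type.
TASK_DURATIONS_MIN: dict[str, tuple[int, int]] = {
    "working_memory_update": (15, 20),
    "inhibitory_control": (12, 18),
    "cognitive_flexibility": (10, 15),
    "tactical_recognition": (20, 25),
    "strategic_planning": (18, 22),
    "integrated_scenarios": (25, 30),
}

#: Feedback action set of the default planner.
DEFAULT_FEEDBACK_ACTIONS = ("reward_tone", "visual_gauge", "difficulty_hint")


@dataclass
class TaskSpec:
    """A training task type with its difficulty-level and duration range."""

    task_type: str
    level_min: int = 0
    level_max: int = 0
    duration_min: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.task_type not in TASK_LEVELS:
            raise ValueError(f"unknown task type {self.task_type!r}; "
                             f"expected one of {sorted(TASK_LEVELS)}")
        lo, hi = TASK_LEVELS[self.task_type]
        if self.level_min == 0 and self.level_max == 0:
            self.level_min, self.level_max = lo, hi
        if (self.level_min, self.level_max) != (lo, hi):
            raise ValueError(
                f"level range ({self.level_min}, {self.level_max}) does not "
                f"match the {self.task_type} range ({lo}, {hi})")
        if self.duration_min == (0, 0):
            self.duration_min = TASK_DURATIONS_MIN[self.task_type]


@dataclass
class DifficultyParams:
    """Difficulty-update gains: alpha_perf on the performance gap,
    beta_load on neural load, and the target performance score."""

    alpha_perf: float = 0.1
    beta_load: float = -0.05
    target_performance: float = 85.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha_perf) and np.isfinite(self.beta_load)):
            raise ValueError("gains must be finite")


@dataclass
class FeedbackPolicy:
    """Finite-horizon planning configuration: action set, discount in
    [0, 1), reward function (state, action, next_state) -> float, and
    planning horizon in steps."""

    actions: tuple = DEFAULT_FEEDBACK_ACTIONS
    discount: float = 0.9
    reward_fn: object = None
    horizon: int = 5

    def __post_init__(self) -> None:
        if not self.actions:
            raise ValueError("action set must be non-empty")
        if not 0 <= self.discount < 1:
            raise ValueError("discount must be in [0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class StabilityCriterion:
    """Exponential-envelope stability check parameters."""

    x_equilibrium: np.ndarray
    v0: float | None = None
    delta_rate: float | None = None

    def __post_init__(self) -> None:
        self.x_equilibrium = np.atleast_1d(
            np.asarray(self.x_equilibrium, dtype=float))
        if self.v0 is not None and self.v0 < 0:
            raise ValueError("v0 must be >= 0")
        if self.delta_rate is not None and self.delta_rate < 0:
            raise ValueError("delta_rate must be >= 0")


def difficulty_step(level: float, current_perf: float, neural_load: float,
                    p: DifficultyParams, task: TaskSpec) -> float:
    """Difficulty(t+1) = level + alpha*(target - current) + beta*load,
    clamped to the task's level range.

    The level is held continuous internally; round at presentation time.
    """
    nxt = (level + p.alpha_perf * (p.target_performance - current_perf)
           + p.beta_load * neural_load)
    clamped = float(np.clip(nxt, task.level_min, task.level_max))
    if clamped != nxt:
        logger.debug("difficulty clamped from %.3f to %.3f for %s",
                     nxt, clamped, task.task_type)
    return clamped


def select_feedback(state, policy: FeedbackPolicy, transition_model):
    """Choose the action maximising expected discounted return over the
    policy horizon.

    ``transition_model(state, action)`` returns either a single next state
    (deterministic) or a list of (probability, next_state) pairs.  Rewards
    come from ``policy.reward_fn(state, action, next_state)``.  Ties are
    broken by action order.
    """
    if policy.reward_fn is None:
        raise ValueError("policy.reward_fn must be set")

    def outcomes(s, a):
        res = transition_model(s, a)
        if isinstance(res, list):
            return res
        return [(1.0, res)]

    @lru_cache(maxsize=None)
    def value(s, steps_left: int) -> float:
        if steps_left == 0:
            return 0.0
        best = -np.inf
        for a in policy.actions:
            q = 0.0
            for prob, s2 in outcomes(s, a):
                q += prob * (policy.reward_fn(s, a, s2)
                             + policy.discount * value(s2, steps_left - 1))
            best = max(best, q)
        return best

    best_action, best_q = None, -np.inf
    for a in policy.actions:
        q = 0.0
        for prob, s2 in outcomes(state, a):
            q += prob * (policy.reward_fn(state, a, s2)
                         + policy.discount * value(s2, policy.horizon - 1))
        if q > best_q + 1e-12:
            best_action, best_q = a, q
    value.cache_clear()
    return best_action


def lyapunov_check(trajectory: np.ndarray, crit: StabilityCriterion,
                   slack: float = 0.01) -> tuple[bool, float | None]:
    """Exponential-stability check of a state trajectory.

    Computes V(t) = ||x(t) - x_eq||^2 and tests V(t) <= V0 * exp(-delta*t)
    for all t (within ``slack`` relative tolerance), with delta taken from
    the criterion or, if unset, fitted by log-linear regression of V(t).
    Returns (stable, fitted_rate).
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 3:
        raise ValueError("trajectory must have length >= 3")
    v = np.sum((traj - crit.x_equilibrium) ** 2, axis=1)
    t = np.arange(v.size, dtype=float)
    v0 = crit.v0 if crit.v0 is not None else float(v[0])
    if np.all(v <= 1e-12):
        return True, None  # already at equilibrium
    pos = v > 0
    fitted = None
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log(v[pos]), 1)
        fitted = float(-slope)
    delta = crit.delta_rate if crit.delta_rate is not None else (fitted or 0.0)
    if delta < 0:
        return False, fitted
    envelope = v0 * np.exp(-delta * t)
    stable = bool(np.all(v <= envelope * (1 + slack) + 1e-12))
    return stable, fitted
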