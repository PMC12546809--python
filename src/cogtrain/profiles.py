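"""Synthetic cohort generation and stratification.

A cohort is a list of :class:`SubjectProfile` objects carrying baseline
scores for the three executive-function components (working memory,
inhibitory control, cognitive flexibility) and the four tactical-cognition
components (situational awareness, pattern recognition, decision accuracy,
strategic planning), plus a responsiveness multiplier that modulates how
strongly the individual responds to training.

Between-profile dispersion is controlled by a coefficient-of-variation
band: each profile draws its own CV uniformly from the band, and each
baseline score is a normal draw with SD = mean * CV, censored to [0, 100]
(censoring events are logged).  Profiles are stratified with k-means and
scored with the silhouette coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .reference import DEFAULT_SCORE_MEANS

logger = logging.getLogger(__name__)

COMPONENTS = tuple(DEFAULT_SCORE_MEANS)

__all__ = ["SubjectProfile", "CohortSpec", "make_cohort", "cluster_profiles",
           "cohort_frame", "COMPONENTS"]


@dataclass
class SubjectProfile:
    """Baseline cognitive scores and training responsiveness for one
    simulated individual.  All baselines are on a 0-100 scale."""

    id: str
    baseline_wm: float
    baseline_ic: float
    baseline_cf: float
    baseline_sa: float
    baseline_pr: float
    baseline_dm: float
    baseline_sp: float
    responsiveness: float = 1.0
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_wm", "baseline_ic", "baseline_cf",
                     "baseline_sa", "baseline_pr", "baseline_dm",
                     "baseline_sp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.responsiveness <= 0:
            raise ValueError("responsiveness must be > 0")

    def baselines(self) -> dict[str, float]:
        """Baseline scores keyed by component name."""
        short = {"working_memory": self.baseline_wm,
                 "inhibitory_control": self.baseline_ic,
                 "cognitive_flexibility": self.baseline_cf,
                 "situational_awareness": self.baseline_sa,
                 "pattern_recognition": self.baseline_pr,
                 "decision_accuracy": self.baseline_dm,
                 "strategic_planning": self.baseline_sp}
        return short


@dataclass
class CohortSpec:
    """Cohort sampling configuration.

    Parameters
    ----------
    n : cohort size (>= 2).
    cv_range : (low, high) coefficient-of-variation band, both in (0, 1).
    score_means : per-component mean baseline score; defaults to the
        reference benchmark pre-training means.
    responsiveness_sd : SD of the (mean-1) responsiveness multiplier.
    seed : RNG seed; identical specs produce bitwise-identical cohorts.
    """

    n: int = 12
    cv_range: tuple[float, float] = (0.15, 0.25)
    score_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MEANS))
    responsiveness_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"cohort size n={self.n} must be >= 2")
        lo, hi = self.cv_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"cv_range={self.cv_range} must satisfy "
                             "0 < low <= high < 1")
        unknown = set(self.score_means) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components in score_means: {unknown}")


_FIELD_BY_COMPONENT = {
    "working_memory": "baseline_wm",
    "inhibitory_control": "baseline_ic",
    "cognitive_flexibility": "baseline_cf",
    "situational_awareness": "baseline_sa",
    "pattern_recognition": "baseline_pr",
    "decision_accuracy": "baseline_dm",
    "strategic_planning": "baseline_sp",
}


def make_cohort(spec: CohortSpec) -> list[SubjectProfile]:
    """Sample ``spec.n`` subject profiles.

    Each profile draws a personal CV uniformly from ``spec.cv_range``; each
    component score is N(mean, (mean*CV)^2) censored to [0, 100].  The
    realized cohort-level CV of every component then falls inside the
    requested band up to sampling slack.  Responsiveness is a positive
    normal multiplier with mean 1.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cv_range
    profiles: list[SubjectProfile] = []
    n_clamped = 0
    for i in range(spec.n):
        cv = rng.uniform(lo, hi)
        values: dict[str, float] = {}
        for comp in COMPONENTS:
            mean = spec.score_means.get(comp, DEFAULT_SCORE_MEANS[comp])
            draw = rng.normal(mean, mean * cv)
            clipped = float(np.clip(draw, 0.0, 100.0))
            if clipped != draw:
                n_clamped += 1
            values[_FIELD_BY_COMPONENT[comp]] = clipped
        resp = rng.normal(1.0, spec.responsiveness_sd)
        resp = float(max(resp, 0.05))
        profiles.append(SubjectProfile(id=f"Model_{i + 1:03d}",
                                       responsiveness=resp, **values))
    if n_clamped:
        logger.info("make_cohort: censored %d baseline draws to [0, 100]",
                    n_clamped)
    return profiles


def cluster_profiles(profiles: list[SubjectProfile], k: int, seed: int = 0,
                     n_restarts: int = 10,
                     ) -> tuple[list[SubjectProfile], float | None]:
    """Stratify profiles with k-means on their baseline scores.

    Runs ``n_restarts`` k-means initialisations and keeps the solution with
    the lowest inertia (earliest restart wins ties).  Returns profiles with
    ``cluster_id`` set and the silhouette coefficient (``None`` for k = 1,
    where cohesion/separation is undefined).
    """
    n = len(profiles)
    if k < 1:
        raise ValueError(f"k={k} must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    X = np.array([[p.baselines()[c] for c in COMPONENTS] for p in profiles])
    if k == 1:
        labelled = [replace(p, cluster_id=0) for p in profiles]
        logger.info("cluster_profiles: k=1, silhouette undefined")
        return labelled, None
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31)))
        km.fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    sil = float(silhouette_score(X, best.labels_)) if k < n else None
    labelled = [replace(p, cluster_id=int(lab))
                for p, lab in zip(profiles, best.labels_)]
    return labelled, sil


def cohort_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Cohort as a DataFrame, one row per profile (CSV/JSON-ready)."""
    return pd.DataFrame([asdict(p) for p in profiles])
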