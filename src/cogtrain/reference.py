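"""Reference benchmark values that calibrate the simulator's defaults.

These are the published validation benchmarks for a 12-profile cognitive
training cohort: per-profile pre/post scores for the three executive
function components (working memory, inhibitory control, cognitive
flexibility), cohort-level pre/post scores for ten tactical-cognition
assessment domains, and pre/post band power for eight scalp region /
frequency-band pairs.  The default cohort means, per-domain improvement
targets, and neural-marker change rates used throughout :mod:`cogtrain`
are derived from these tables, so a default simulation run lands near the
benchmark numbers in expectation.

Scores are on a 0-100 scale; band powers are in µV².
"""

from __future__ import annotations

import pandas as pd

#: Executive-function benchmark: per-profile (pre, post) for WM / IC / CF.
EF_BENCHMARK: dict[str, list[tuple[float, float]]] = {
    "working_memory": [
        (72.4, 89.3), (78.6, 91.4), (69.8, 86.7), (75.1, 88.9),
        (73.9, 90.2), (76.4, 89.8), (71.2, 87.6), (77.8, 92.1),
        (74.3, 88.4), (72.7, 89.7), (75.9, 90.6), (73.1, 88.2),
    ],
    "inhibitory_control": [
        (68.1, 85.7), (74.2, 88.9), (66.4, 83.2), (71.8, 87.4),
        (69.7, 86.1), (73.5, 89.3), (67.9, 84.8), (75.1, 90.2),
        (70.6, 85.9), (68.8, 87.1), (72.3, 88.7), (69.4, 86.3),
    ],
    "cognitive_flexibility": [
        (65.9, 87.2), (71.3, 89.6), (63.7, 84.1), (68.5, 86.8),
        (67.2, 88.4), (70.1, 87.9), (64.8, 85.7), (72.4, 90.3),
        (66.9, 86.5), (65.4, 87.8), (69.7, 88.9), (66.1, 86.2),
    ],
}

#: Published per-cell improvement percentages of the EF benchmark.  Four
#: cells (marked in tests) are internally inconsistent with their own
#: pre/post values at one-decimal rounding; they are kept verbatim here.
EF_BENCHMARK_PRINTED_PCT: dict[str, list[float]] = {
    "working_memory": [23.3, 16.3, 24.2, 18.4, 22.1, 17.5,
                       23.0, 18.4, 19.0, 23.4, 19.3, 20.7],
    "inhibitory_control": [25.9, 19.8, 25.3, 21.7, 23.5, 21.5,
                           24.9, 20.1, 21.7, 26.6, 22.7, 24.3],
    "cognitive_flexibility": [32.3, 25.7, 32.0, 26.7, 31.5, 25.4,
                              32.3, 24.7, 29.3, 34.3, 27.5, 30.4],
}

#: Tactical-cognition benchmark: domain -> (pre, post) cohort scores.
TC_BENCHMARK: dict[str, tuple[float, float]] = {
    "pattern_recognition": (73.2, 94.1),
    "strategic_planning": (68.7, 89.6),
    "decision_accuracy": (71.4, 90.3),
    "reaction_time_efficiency": (76.8, 89.7),
    "situational_awareness": (69.9, 88.4),
    "tactical_flexibility": (72.1, 91.2),
    "risk_assessment": (74.6, 87.9),
    "communication_efficiency": (70.3, 86.7),
    "pressure_management": (67.8, 85.1),
    "adaptive_strategy": (71.9, 89.8),
}

TC_BENCHMARK_PRINTED_PCT: dict[str, float] = {
    "pattern_recognition": 28.5,
    "strategic_planning": 30.4,
    "decision_accuracy": 26.5,
    "reaction_time_efficiency": 16.8,
    "situational_awareness": 26.5,
    "tactical_flexibility": 26.5,
    "risk_assessment": 17.8,
    "communication_efficiency": 23.3,
    "pressure_management": 25.5,
    "adaptive_strategy": 24.9,
}

#: Neural-marker benchmark: (region, band) -> (pre power, post power) µV².
NEURAL_BENCHMARK: dict[tuple[str, str], tuple[float, float]] = {
    ("frontal_fz", "theta"): (12.4, 15.8),
    ("frontal_f3f4", "alpha"): (18.7, 22.1),
    ("parietal_pz", "alpha"): (21.3, 25.7),
    ("central_cz", "beta"): (14.9, 17.8),
    ("occipital_oz", "gamma"): (8.6, 10.4),
    ("temporal_t7t8", "theta"): (11.2, 13.9),
    ("fronto_central", "beta"): (16.8, 20.2),
    ("parieto_occipital", "alpha"): (19.4, 23.1),
}

NEURAL_BENCHMARK_PRINTED_PCT: dict[tuple[str, str], float] = {
    ("frontal_fz", "theta"): 27.4,
    ("frontal_f3f4", "alpha"): 18.2,
    ("parietal_pz", "alpha"): 20.7,
    ("central_cz", "beta"): 19.5,
    ("occipital_oz", "gamma"): 20.9,
    ("temporal_t7t8", "theta"): 24.1,
    ("fronto_central", "beta"): 20.2,
    ("parieto_occipital", "alpha"): 19.1,
}

#: Conventional EEG band edges in Hz (gamma capped at 50 Hz to match the
#: 0.5-50 Hz content of the synthetic signals and the marker benchmark).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Default cohort baseline means: EF component means from the EF benchmark
#: pre columns, TC component means from the TC benchmark pre column.
DEFAULT_SCORE_MEANS: dict[str, float] = {
    "working_memory": 74.3,
    "inhibitory_control": 70.6,
    "cognitive_flexibility": 67.7,
    "situational_awareness": 69.9,
    "pattern_recognition": 73.2,
    "decision_accuracy": 71.4,
    "strategic_planning": 68.7,
}

#: Default per-domain fractional improvement targets for the collaborative
#: condition: benchmark summary-row change of the EF components and the
#: printed cohort change of the four core TC domains.
DEFAULT_EFFECT_TARGETS: dict[str, float] = {
    "working_memory": 0.204,
    "inhibitory_control": 0.231,
    "cognitive_flexibility": 0.293,
    "situational_awareness": 0.265,
    "pattern_recognition": 0.285,
    "decision_accuracy": 0.265,
    "strategic_planning": 0.304,
}

EF_DOMAINS = ("working_memory", "inhibitory_control", "cognitive_flexibility")
TC_DOMAINS = ("situational_awareness", "pattern_recognition",
              "decision_accuracy", "strategic_planning")


def ef_benchmark_frame() -> pd.DataFrame:
    """EF benchmark as a tidy frame (profile, domain, pre, post)."""
    rows = []
    for domain, pairs in EF_BENCHMARK.items():
        for i, (pre, post) in enumerate(pairs):
            rows.append({"profile": f"Model_{i + 1:03d}", "domain": domain,
                         "pre": pre, "post": post})
    return pd.DataFrame(rows)


def tc_benchmark_frame() -> pd.DataFrame:
    """TC benchmark as a tidy frame (domain, pre, post)."""
    return pd.DataFrame(
        [{"domain": d, "pre": pre, "post": post}
         for d, (pre, post) in TC_BENCHMARK.items()]
    )


def neural_benchmark_frame() -> pd.DataFrame:
    """Neural-marker benchmark as a tidy frame (region, band, pre, post)."""
    return pd.DataFrame(
        [{"region": r, "band": b, "pre": pre, "post": post}
         for (r, b), (pre, post) in NEURAL_BENCHMARK.items()]
    )
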