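"""Run-configuration loading (YAML or JSON).

A configuration file may carry a ``cohort`` section (fields of
:class:`~cogtrain.profiles.CohortSpec`) and a ``protocol`` section (fields
of :class:`~cogtrain.experiment.ProtocolConfig`); omitted fields take the
calibrated defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .experiment import ProtocolConfig, default_protocol_cohort_spec
from .profiles import CohortSpec

__all__ = ["load_config"]


def load_config(path: str | Path,
                seed: int | None = None) -> tuple[CohortSpec, ProtocolConfig]:
    """Read a YAML/JSON run configuration into (CohortSpec, ProtocolConfig).

    ``seed``, when given, overrides both sections' seeds.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    protocol_kwargs = dict(raw.get("protocol", {}))
    if "cv_range" in cohort_kwargs:
        cohort_kwargs["cv_range"] = tuple(cohort_kwargs["cv_range"])
    if "conditions" in protocol_kwargs:
        protocol_kwargs["conditions"] = tuple(protocol_kwargs["conditions"])
    if seed is not None:
        cohort_kwargs["seed"] = seed
        protocol_kwargs["seed"] = seed
    if cohort_kwargs:
        cohort = CohortSpec(**cohort_kwargs)
    else:
        cohort = default_protocol_cohort_spec(seed=seed or 0)
    protocol = ProtocolConfig(**protocol_kwargs)
    return cohort, protocol
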