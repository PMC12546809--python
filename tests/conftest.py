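import numpy as np
import pytest

from cogtrain.profiles import CohortSpec, SubjectProfile, make_cohort


@pytest.fixture(scope="session")
def small_cohort() -> list[SubjectProfile]:
    return make_cohort(CohortSpec(n=12, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def flat_profile(pid: str = "P1", score: float = 70.0,
                 responsiveness: float = 1.0, **overrides) -> SubjectProfile:
    """A profile with every baseline at ``score`` unless overridden."""
    kwargs = {f"baseline_{k}": score
              for k in ("wm", "ic", "cf", "sa", "pr", "dm", "sp")}
    kwargs.update(overrides)
    return SubjectProfile(id=pid, responsiveness=responsiveness, **kwargs)
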