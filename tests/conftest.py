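import numpy as np
import pytest

from igpg import synthetic
from igpg.anthropometry import SLOT_NAMES, BodyParameters
from igpg.synthetic import DEFAULT_SLOT_RANGES


@pytest.fixture(scope="session")
def fixture_sessions():
    """Packaged nine-subject trial records: (general, individualized)."""
    return synthetic.load_fixture("general"), synthetic.load_fixture("individualized")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject synthetic cohort shared by pipeline-level tests."""
    return synthetic.generate_cohort(synthetic.CohortConfig(n_subjects=6, seed=7))


def random_body(rng: np.random.Generator, subject_id: str = "") -> BodyParameters:
    values = np.empty(len(SLOT_NAMES))
    for k, slot in enumerate(SLOT_NAMES):
        lo, hi = DEFAULT_SLOT_RANGES[slot]
        values[k] = float(rng.integers(0, 2)) if slot == "sex" else rng.uniform(lo, hi)
    return BodyParameters(values=values, subject_id=subject_id)
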