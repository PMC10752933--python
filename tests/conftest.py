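import numpy as np
import pandas as pd
import pytest

from glucast.preprocessing import preprocess_participant
from glucast.synthetic import (
    default_camp_schedule,
    generate_cohort,
    sample_statics,
)
from glucast.training import Cohort


@pytest.fixture(scope="session")
def statics_one():
    """One deterministic participant."""
    return sample_statics(1, seed=42)[0]


@pytest.fixture(scope="session")
def schedule():
    return default_camp_schedule(6)


@pytest.fixture(scope="session")
def camp_streams():
    """Full-size camp cohort: 14 children, 6 days."""
    return generate_cohort(14, 6, seed=1)


@pytest.fixture(scope="session")
def camp_cohort(camp_streams) -> Cohort:
    streams, statics = camp_streams
    splits = {raw.participant_id: preprocess_participant(raw) for raw in streams}
    return Cohort.assemble(
        splits, {st.participant_id: st for st in statics}, subset="six"
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """Three children, three days: fast fixture for training-loop tests."""
    streams, statics = generate_cohort(3, 3, seed=7, truncate_one=False)
    splits = {raw.participant_id: preprocess_participant(raw) for raw in streams}
    return Cohort.assemble(
        splits, {st.participant_id: st for st in statics}, subset="six"
    )
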