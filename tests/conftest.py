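import numpy as np
import pytest

from cortexmicro import pipeline, synthdata


@pytest.fixture(scope="session")
def study_cohort():
    """Default-size synthetic cohort (14/15/17) with scored questionnaires."""
    participants, items = synthdata.generate_cohort(seed=20240101)
    return participants, items


@pytest.fixture(scope="session")
def planted_dataset():
    """n=50/group cohort with the default planted effect, ingested for PLS."""
    spec = synthdata.CohortSpec(group_sizes=(50, 50, 50))
    participants, _ = synthdata.generate_cohort(spec, seed=11)
    wide = synthdata.generate_brain(participants, seed=12)
    wide = wide.merge(
        participants[["id", "strength", "degree", "age_months"]], on="id"
    )
    return participants, pipeline.ingest_roi_table(wide)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
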