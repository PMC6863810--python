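import numpy as np
import pandas as pd
import pytest

from abmprobe.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but structurally complete cohort: 24 participants,
    40-trial measurements, 20-trial training blocks."""
    config = CohortConfig(
        n_participants=24,
        block_sizes=(12, 8, 4),
        n_measurement_trials=40,
        trials_per_block=20,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    """Questionnaire table with group labels attached."""
    groups = small_cohort.ground_truth[["id", "group"]].rename(
        columns={"id": "participant_id"}
    )
    return small_cohort.questionnaires.merge(groups, on="participant_id")
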