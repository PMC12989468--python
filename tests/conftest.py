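"""Shared fixtures: a small synthetic study generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liftbiome.config import (
    CohortConfig,
    MicrobiomeSimConfig,
    TrainingSimConfig,
)
from liftbiome import simulate as sim
from liftbiome import strength as strength_mod


SMALL_COHORT = CohortConfig(
    n_enrolled=40,
    n_dropout=6,
    n_quality_excluded=2,
    n_validation_excluded=2,
    seed=11,
)

SMALL_MICROBIOME = MicrobiomeSimConfig(
    n_asv=80,
    mean_depth=4000.0,
    n_planted_up=6,
    n_planted_down=4,
    seed=13,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return sim.generate_cohort(SMALL_COHORT)


@pytest.fixture(scope="session")
def small_logs(small_cohort):
    return sim.generate_training_logs(
        small_cohort, TrainingSimConfig(seed=12)
    )


@pytest.fixture(scope="session")
def small_metrics(small_cohort, small_logs):
    sessions, fitness = small_logs
    table = strength_mod.strength_metrics_table(sessions, fitness)
    final = set(
        small_cohort.loc[
            small_cohort["status"] == "final", "participant"
        ]
    )
    return table[table["participant"].isin(final)].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_asv(small_cohort, small_metrics):
    scores = small_metrics.set_index("participant")["percent_gain"]
    counts, metadata, taxonomy, truth = sim.generate_asv_tables(
        small_cohort, scores, SMALL_MICROBIOME
    )
    return counts, metadata.set_index("sample-id"), taxonomy, truth
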