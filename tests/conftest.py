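import warnings

import numpy as np
import pandas as pd
import pytest

from respmon.gridding import TrainingStats
from respmon.pipeline import process_cohort
from respmon.schema import Schema, StayRecord, default_schema
from respmon.simulate import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")

T0 = pd.Timestamp("2014-03-01 12:00:00")


def make_stay(obs_bins: dict, n_bins: int = 48, patient_id: str = "p0", **kwargs) -> StayRecord:
    """Stay with HR at every bin start plus extra observations given as
    variable -> list of (minutes, value)."""
    observations = {
        "hr": (
            T0 + pd.to_timedelta(np.arange(n_bins) * 5, unit="m"),
            np.full(n_bins, 80.0),
        )
    }
    for vid, pairs in obs_bins.items():
        mins = [m for m, _ in pairs]
        vals = [v for _, v in pairs]
        observations[vid] = (
            T0 + pd.to_timedelta(mins, unit="m"),
            np.asarray(vals, dtype=float),
        )
    defaults = dict(
        patient_id=patient_id,
        admission_time=T0,
        discharge_time=T0 + pd.Timedelta(minutes=5 * n_bins),
        observations=observations,
    )
    defaults.update(kwargs)
    return StayRecord(**defaults)


@pytest.fixture(scope="session")
def schema() -> Schema:
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    stays, truth = simulate_cohort(SimConfig(n_stays=40, seed=11))
    return stays, truth


@pytest.fixture(scope="session")
def small_stats(small_cohort, schema):
    stays, _ = small_cohort
    return TrainingStats.fit(stays, schema)


@pytest.fixture(scope="session")
def processed_small(small_cohort, schema, small_stats):
    stays, truth = small_cohort
    cohort = process_cohort(stays, schema, stats=small_stats)
    return cohort, truth
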