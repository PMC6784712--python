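"""Shared fixtures: pilot tables, simulated recordings and a refit cohort.

The heavier simulation fixtures are session-scoped; the cohort used for
pipeline-recovery checks uses 3-hour nights at 25 Hz sampling — the same
generator as the full-rate default, scaled for the test suite.
"""
from __future__ import annotations

import numpy as np
import pytest

from lcsleep.osa_model import LopoResult, fit_lopo
from lcsleep.signal_io import load_pilot_tables
from lcsleep.simulator import SimulationConfig, simulate_cohort, simulate_recording

TEST_FS = 25.0
TEST_NIGHT_H = 3.0


def small_config(**kw) -> SimulationConfig:
    base = dict(duration_h=TEST_NIGHT_H, sample_rate_hz=TEST_FS)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tables():
    return load_pilot_tables()


@pytest.fixture(scope="session")
def quiet_night():
    """A 3-h event-free simulated recording."""
    rec, truth = simulate_recording(small_config(target_ahi=0.0, seed=101))
    assert truth.true_ahi == 0.0
    return rec


@pytest.fixture(scope="session")
def severe_night():
    """A 3-h simulated recording with a high event rate."""
    rec, truth = simulate_recording(small_config(target_ahi=30.0, seed=102))
    return rec, truth


@pytest.fixture(scope="session")
def cohort_df():
    """Feature/label table for a 20-subject, 2-night simulated cohort."""
    cohort = simulate_cohort(20, 2, seed=7, config=small_config())
    return cohort.feature_table()


@pytest.fixture(scope="session")
def lopo_result(cohort_df) -> LopoResult:
    X = cohort_df[[f"X{i}" for i in range(1, 7)]].to_numpy()
    return fit_lopo(
        cohort_df.subject_id.to_numpy(),
        X,
        cohort_df.abnormal.to_numpy(),
        cohort_df.true_ahi.to_numpy(),
        night_keys=cohort_df.night.to_numpy(),
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_pipeline(lopo_result):
    return lopo_result.final_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
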