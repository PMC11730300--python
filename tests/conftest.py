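"""Shared fixtures: a session-calibrated surrogate model and record factories."""

from __future__ import annotations

import numpy as np
import pytest

from ecgaging import morphology_from_age, simulate_ecg, surrogate_model
from ecgaging.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def model():
    """Calibrated surrogate age model at the default sampling rate (cached)."""
    return surrogate_model(fs=400.0)


@pytest.fixture(scope="session")
def record_factory():
    """Factory for generator records: record_factory(age, sex, noise_sd, seed)."""

    def make(age=50.0, sex="male", noise_sd=0.0, seed=None, heart_rate=None, fs=400.0):
        rng = np.random.default_rng(seed) if seed is not None else None
        morph = morphology_from_age(age, sex, rng=rng, heart_rate=heart_rate)
        return simulate_ecg(morph, fs=fs, noise_sd=noise_sd, seed=rng)

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with records, reused by IO/prediction tests."""
    cfg = CohortConfig(n_subjects=8, seed=123)
    table, records = simulate_cohort(cfg, with_records=True)
    return cfg, table, records


@pytest.fixture(scope="session")
def table_cohort():
    """Medium table-only cohort for risk-statistics tests."""
    cfg = CohortConfig(n_subjects=2000, seed=77)
    table, _ = simulate_cohort(cfg, with_records=False)
    return cfg, table
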