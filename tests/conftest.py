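"""Shared fixtures: small deterministic cohorts and detector configs."""

from __future__ import annotations

import numpy as np
import pytest

from eyefatigue.config import CohortConfig
from eyefatigue.gaze_features import DetectorConfig
from eyefatigue.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject main-arm cohort with gaze windows (session-cached)."""
    return generate_cohort(CohortConfig(n_subjects=12, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """The full 105-subject main-arm cohort, gaze included (session-cached)."""
    return generate_cohort(CohortConfig(seed=20240917))


@pytest.fixture(scope="session")
def default_cohort_tables(default_cohort):
    """(unified features + fatigue labels) merged table for the default cohort."""
    from eyefatigue.gaze_features import extract_cohort_features, unify_feature_table
    from eyefatigue.ground_truth import fatigue_table

    feats = extract_cohort_features(default_cohort.gaze)
    fatigue, weights = fatigue_table(default_cohort.optometry)
    merged = unify_feature_table(feats).merge(fatigue, on=["subject", "epoch"])
    return merged, weights


@pytest.fixture
def detector():
    return DetectorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
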