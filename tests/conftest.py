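"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import pytest

from refwait.cohort import derive_gold_pairs, filter_short_notes
from refwait.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    """No confounding events: every patient is one note + one claim."""
    return SyntheticConfig(notes_per_specialty=200, multi_event_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_labeled(clean_config, clean_cohort):
    notes, claims, _ = clean_cohort
    filtered = filter_short_notes(notes)
    return derive_gold_pairs(filtered, claims, clean_config.study_year)


@pytest.fixture(scope="session")
def confounded_config() -> SyntheticConfig:
    return SyntheticConfig(notes_per_specialty=200, multi_event_rate=0.3, seed=23)


@pytest.fixture(scope="session")
def confounded_cohort(confounded_config):
    return generate_cohort(confounded_config)
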