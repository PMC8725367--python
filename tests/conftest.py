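"""Shared fixtures: one moderately sized simulated survey, calibrated once.

The heavy objects are session-scoped so the suite fits comfortably in a
single-CPU run; tests that need different generating conditions build
their own small datasets.
"""

import pytest

from mdsmetrics import (
    GeneratingSpec,
    estimate_abilities,
    fit_pcm,
    simulate_survey,
)


@pytest.fixture(scope="session")
def default_spec():
    return GeneratingSpec(seed=0)  # n=2000, 15 items, 5 categories, theta~N(-1, 1.2^2)


@pytest.fixture(scope="session")
def dataset(default_spec):
    return simulate_survey(default_spec)


@pytest.fixture(scope="session")
def capacity_fit(dataset):
    return fit_pcm(dataset.capacity_responses)


@pytest.fixture(scope="session")
def capacity_persons(dataset, capacity_fit):
    return estimate_abilities(dataset.capacity_responses, capacity_fit.items)


@pytest.fixture(scope="session")
def clean_dataset():
    """Complete-data survey (no missingness) for residual-based diagnostics."""
    return simulate_survey(GeneratingSpec(seed=3, missing_rate=0.0))


@pytest.fixture(scope="session")
def clean_fit(clean_dataset):
    return fit_pcm(clean_dataset.capacity_responses)


@pytest.fixture(scope="session")
def clean_persons(clean_dataset, clean_fit):
    return estimate_abilities(clean_dataset.capacity_responses, clean_fit.items)
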