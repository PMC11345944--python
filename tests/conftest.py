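"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gastropk import ivivp, pkcore

# Deterministic hypothesis runs: derandomized, no deadline flakiness on a
# loaded CI box, modest example counts to respect the time budget.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pop():
    return pkcore.default_poppk()


@pytest.fixture(scope="session")
def typical(pop):
    """Typical 70 kg subject (capsule absorption parameters)."""
    return pkcore.covariate_scale(pop, 70.0)


@pytest.fixture(scope="session")
def typical_tablet(pop):
    return pkcore.covariate_scale(pop, 70.0, formulation="tablet")


@pytest.fixture(scope="session")
def gi_cfg():
    return ivivp.default_gi_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
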