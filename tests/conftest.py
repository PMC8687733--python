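"""Shared fixtures: solved temperature fields and the seeded fixture cohort
are expensive, so they are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from wdrtherm.protocols import make_single_stim
from wdrtherm.thermal import SkinThermalParams, solve_skin_temperature
from wdrtherm.wdr_model import CohortSpec, class_params, generate_cohort


@pytest.fixture(scope="session")
def skin():
    return SkinThermalParams()


@pytest.fixture(scope="session")
def mhc_params():
    return class_params("MHC")


@pytest.fixture(scope="session")
def hot_protocol():
    return make_single_stim("hot", 1.0)


@pytest.fixture(scope="session")
def cold_protocol():
    return make_single_stim("cold", 1.0)


@pytest.fixture(scope="session")
def hot_field(hot_protocol, skin):
    return solve_skin_temperature(hot_protocol, skin)


@pytest.fixture(scope="session")
def cold_field(cold_protocol, skin):
    return solve_skin_temperature(cold_protocol, skin)


@pytest.fixture(scope="session")
def fixture_cohort(skin):
    """The seeded 37-neuron fixture cohort run through the full battery."""
    return generate_cohort(CohortSpec(), seed=7, sp=skin)
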