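"""Shared fixtures: planning parameters of the worked example and small
simulated p-value matrices reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from gsfutility import (
    FutilityPair,
    interim_calendar_time,
    local_levels,
    simulate_pvalue_matrix,
)
from gsfutility.designs import Approach
from gsfutility.renaal import design_spec, planning_params, scenario_params


@pytest.fixture(scope="session")
def pocock_levels():
    return local_levels(0.025, 0.5, "pocock")


@pytest.fixture(scope="session")
def small_planning():
    """Planning scenario at a reduced per-group size for fast simulation."""
    return planning_params(200)


@pytest.fixture(scope="session")
def interim_small(small_planning):
    return interim_calendar_time(small_planning, 0.5)


@pytest.fixture(scope="session")
def matrix_h1_small(small_planning, interim_small):
    """800 trials under planning assumptions, n=200 per group."""
    return simulate_pvalue_matrix(
        small_planning, n_sims=800, seed=421, interim_months=interim_small,
        scenario="planning",
    )


@pytest.fixture(scope="session")
def matrix_star_small(interim_small):
    """800 trials under the theta* scenario (MC hazard ratio 1.2), n=200."""
    return simulate_pvalue_matrix(
        scenario_params(1.2, 200), n_sims=800, seed=421,
        interim_months=interim_small, scenario="theta_star",
    )


@pytest.fixture(scope="session")
def spec_a1():
    return design_spec(Approach.IUT_SUP_SUP)


@pytest.fixture(scope="session")
def spec_a3():
    return design_spec(Approach.SINGLE_EP_TWO_FUT)
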