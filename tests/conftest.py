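"""Shared fixtures.  The expensive whole-cell runs are session-scoped and
reused by the unit, property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from cicrsim import load_default_parameters, load_initial_state
from cicrsim.cell import CellModel
from cicrsim import experiments as ex


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def y0(params):
    return load_initial_state(params)


@pytest.fixture(scope="session")
def model(params):
    return CellModel(params)


@pytest.fixture(scope="session")
def gain_pair(model):
    """Standard 50 ms +10 mV control/ryanodine pair with gain and CDI."""
    return ex.run_gain_pair(model)


@pytest.fixture(scope="session")
def s1s2_scan(model):
    """Paired-stimulus scan over the printed T2 range."""
    return ex.run_s1s2(model, t2_list=range(50, 275, 25))


@pytest.fixture(scope="session")
def long_pulse(model):
    """Long-pulse (800 ms / 0.33 Hz) run, scaled down to 4 pulses."""
    return ex.long_pulse_balance(model, n_pulses=4)


@pytest.fixture(scope="session")
def staircase(model):
    """Short-pulse (100 ms / 0.33 Hz) train, scaled down to 12 pulses."""
    return ex.short_pulse_staircase(model, n_pulses=12)


@pytest.fixture(scope="session")
def ablation(model):
    return ex.sensor_ablation(model, n_pulses=10)


@pytest.fixture(scope="session")
def caffeine(model):
    return ex.caffeine_study(model)
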