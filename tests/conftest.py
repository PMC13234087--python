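"""Shared fixtures: the default synthetic patient and one converged run.

The baseline run at the default integrator settings (dt = 1 ms) is computed
once per session and shared by the solver, metrics and acceptance tests.
"""

import numpy as np
import pytest

from cardioloop.network import IntegratorConfig
from cardioloop.solver import run_cycles
from cardioloop.synthetic import (SimSettings, SyntheticPatientSpec,
                                  build_network, resolve)


@pytest.fixture(scope="session")
def patient_spec():
    return resolve(SyntheticPatientSpec())


@pytest.fixture(scope="session")
def baseline_network(patient_spec):
    return build_network(patient_spec)


@pytest.fixture(scope="session")
def baseline_run(baseline_network):
    cycles, periodic = run_cycles(baseline_network, IntegratorConfig(),
                                  max_cycles=12)
    return cycles, periodic


@pytest.fixture(scope="session")
def baseline_cycle(baseline_run):
    cycles, _ = baseline_run
    return cycles[-1]


@pytest.fixture(scope="session")
def reduced_sim():
    return SimSettings.reduced()
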