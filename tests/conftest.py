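"""Shared simulation fixtures.

The conductance-based runs are the expensive part of the suite, so the
standard scenarios are simulated once per session and shared between
the behavioural unit tests and the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from pulsegate.network import build_network
from pulsegate.pulses import generate_pulse_times
from pulsegate.simulate import simulate

TRANSIENT = 2000.0  # ms discarded by consumers of these fixtures


@pytest.fixture(scope="session")
def fs_si_ib_40hz():
    """FS-SI-IB network driven at 40 Hz for 10 s."""
    spec = build_network("fs_si_ib")
    train = generate_pulse_times(40.0, 0.0, 10_000.0)
    res = simulate(spec, {"input1": train}, 10_000.0)
    return spec, train, res


@pytest.fixture(scope="session")
def fs_si_ib_60hz():
    """FS-SI-IB network driven at 60 Hz for 10 s (2:7 plateau)."""
    spec = build_network("fs_si_ib")
    train = generate_pulse_times(60.0, 0.0, 10_000.0)
    res = simulate(spec, {"input1": train}, 10_000.0)
    return spec, train, res


@pytest.fixture(scope="session")
def full4_driven_40hz():
    """Full four-cell network driven at 40 Hz for 10 s."""
    spec = build_network("full4")
    train = generate_pulse_times(40.0, 0.0, 10_000.0)
    res = simulate(spec, {"input1": train}, 10_000.0)
    return spec, train, res


@pytest.fixture(scope="session")
def fs_si_2inputs_run():
    """FS-SI network with 40 Hz and 16.357 Hz periodic inputs, 8 s."""
    spec = build_network("fs_si_2inputs")
    drives = {
        "input1": generate_pulse_times(40.0, 0.0, 8_000.0),
        "input2": generate_pulse_times(16.357, 0.0, 8_000.0),
    }
    res = simulate(spec, drives, 8_000.0)
    return spec, drives, res


def post_transient(events, cutoff=TRANSIENT):
    ev = np.asarray(events)
    return ev[ev > cutoff]
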