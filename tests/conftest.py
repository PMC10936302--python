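"""Shared fixtures: one trained model and one protocol stream per session.

The heavy artifacts (a 300 s constant-speed training stream, the fitted
model, and the full 18-trial protocol stream) are built once and reused.
"""

import numpy as np
import pytest

import gaitintent as gi


@pytest.fixture(scope="session")
def template():
    return gi.default_template()


@pytest.fixture(scope="session")
def training_stream(template):
    """Five minutes of constant-speed walking at the 1.4 m/s baseline."""
    return gi.simulate(template, gi.constant_speed_profile(1.4, 300.0), seed=2)


@pytest.fixture(scope="session")
def trained_results(training_stream):
    return gi.CyclostationaryGaitModel.from_dataframe(training_stream.frames).fit()


@pytest.fixture(scope="session")
def protocol():
    return gi.build_standard_protocol()


@pytest.fixture(scope="session")
def protocol_stream(template, protocol):
    return gi.simulate(template, protocol, seed=3)


@pytest.fixture(scope="session")
def protocol_phase_timesteps(protocol_stream):
    return gi.segment_stream(protocol_stream.frames)
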