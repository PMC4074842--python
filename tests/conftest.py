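"""Shared fixtures: a small seeded tumor/normal scenario used across tests."""

import pytest

from somaticscan import simdata as sd
from somaticscan.benchmarks import compact_scenario


@pytest.fixture(scope="session")
def scenario():
    """Two 200 kb chromosomes at 40x carrying every event class."""
    config, ref = compact_scenario(seed=7)
    normal, tumor, truth = sd.simulate_pair(config, ref)
    return {"config": config, "reference": ref,
            "normal": normal, "tumor": tumor, "truth": truth}
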