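import json

import pytest
from hypothesis import settings

from spikestage import DeviceSpec, parse_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def minimal_doc() -> str:
    """One IZH neuron, one stimulus, one report: the smallest valid network."""
    return json.dumps(
        {
            "seed": 1,
            "groups": [{"name": "g", "model": "izh", "count": 1, "pattern": "RS"}],
            "stimuli": [
                {"group": "g", "kind": "current", "amplitude": 10.0,
                 "start": 0, "end": 100}
            ],
            "reports": [
                {"name": "raster", "group": "g", "value": "spike", "sink": "memory"}
            ],
        }
    )


@pytest.fixture
def minimal_network(minimal_doc):
    return parse_network(minimal_doc)


@pytest.fixture
def one_device():
    return [DeviceSpec("cpu0", 1000.0, 1)]


@pytest.fixture
def two_devices():
    return [DeviceSpec("gpu0", 1544.0, 2), DeviceSpec("cpu0", 1000.0, 1)]
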