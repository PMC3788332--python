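"""Firing-pattern validation suite.

Drives a single neuron of each family (IZH and hybrid LIF) with its
canonical suprathreshold current for one simulated second through the
full staged engine, records the voltage trace and spike raster, and
classifies the resulting train as regular-spiking, fast-spiking or
bursting.  This reproduces the standard three-pattern model validation:
each family must express all three classes under its canonical
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .distribution import DeviceSpec
from .engine import run
from .network import parse_network
from .neurons import CANONICAL_DRIVE, classify_pattern

__all__ = ["PatternResult", "run_pattern", "run_suite", "PATTERNS", "FAMILIES"]

FAMILIES = ("izh", "lif")
PATTERNS = ("RS", "FS", "B")


@dataclass
class PatternResult:
    family: str
    pattern: str
    spike_steps: list[int]
    classification: str
    trace_csv: str  # voltage trace of the driven neuron
    raster_csv: str


def _suite_document(family: str, pattern: str, duration: int) -> str:
    return json.dumps(
        {
            "seed": 0,
            "groups": [
                {"name": "cell", "model": family, "count": 1, "pattern": pattern}
            ],
            "stimuli": [
                {
                    "group": "cell",
                    "kind": "current",
                    "amplitude": CANONICAL_DRIVE[family][pattern],
                    "start": 0,
                    "end": duration,
                }
            ],
            "reports": [
                {"name": "trace", "group": "cell", "value": "voltage",
                 "sink": f"{family}_{pattern}_trace.csv"},
                {"name": "raster", "group": "cell", "value": "spike",
                 "sink": f"{family}_{pattern}_raster.csv"},
            ],
        }
    )


def run_pattern(
    family: str, pattern: str, duration_ms: int = 1000
) -> PatternResult:
    """Run one family/pattern cell through the engine and classify it."""
    net = parse_network(_suite_document(family, pattern, duration_ms))
    res = run(net, [DeviceSpec("cpu0", 1000.0, 1)], duration_ms)
    spikes = [int(s) for s, _ in res.raster("raster")]
    return PatternResult(
        family=family,
        pattern=pattern,
        spike_steps=spikes,
        classification=classify_pattern(spikes, window_ms=duration_ms),
        trace_csv=res.reports["trace"],
        raster_csv=res.reports["raster"],
    )


def run_suite(duration_ms: int = 1000) -> list[PatternResult]:
    """All six family x pattern combinations."""
    return [
        run_pattern(f, p, duration_ms) for f in FAMILIES for p in PATTERNS
    ]
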