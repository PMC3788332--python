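"""Reporters: subscribe to published buffers, aggregate, write sinks.

A report names a set of elements and a value kind (voltage, spike, input
current, synaptic current, or spike count).  After distribution each
requested element is resolved to exactly one data source — the publisher
of the producing stage on the element's device, plus the device-local
index — identified by a string name such as ``neuron_out[2]``.  One
reporter is instantiated per machine (this engine hosts a single
machine); it acquires all its subscriptions each step, extracts and
aggregates, and appends to its sinks.

Sink formats are plain CSV with ``#``-prefixed metadata lines (network
hash, seed, dt): spike rasters as two columns ``step,neuron`` (network
IDs, ascending within a step), dense traces as one row per cadence tick
with columns in ascending element-ID order, spike counts as
``step,count`` reduced across devices before writing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import ReportSpec
from .scopes import ConfigurationError

__all__ = ["ReportSources", "Reporter", "resolve_sources"]

_PUBLISHER_OF_VALUE = {
    "voltage": "neuron_out",
    "spike": "neuron_out",
    "spike_count": "neuron_out",
    "input_current": "input_current",
    "synaptic_current": "syn_current",
}


@dataclass
class ReportSources:
    """Resolved data sources of one report: per device, indices and columns."""

    spec: ReportSpec
    publisher_kind: str
    # device -> (local indices, column positions in the output row)
    per_device: dict[int, tuple[np.ndarray, np.ndarray]]
    sorted_ids: np.ndarray


def resolve_sources(
    reports: Sequence[ReportSpec],
    neuron_device: Mapping[int, int],
    local_maps: Sequence[Mapping[int, int]],
) -> list[ReportSources]:
    """Map every reported element to its device-local source.

    Unknown elements are a configuration error naming every offender.
    Each element resolves to exactly one source; the index sets of the
    per-device sources partition the report's element list.
    """
    out = []
    for spec in reports:
        unknown = [e for e in spec.element_ids if e not in neuron_device]
        if unknown:
            raise ConfigurationError(
                f"report {spec.name!r} references unknown elements: {unknown}"
            )
        sorted_ids = np.array(sorted(spec.element_ids), dtype=np.int64)
        col_of_id = {int(e): k for k, e in enumerate(sorted_ids)}
        per_device: dict[int, list[tuple[int, int]]] = {}
        for e in map(int, sorted_ids):
            d = neuron_device[e]
            per_device.setdefault(d, []).append((local_maps[d][e], col_of_id[e]))
        packed = {
            d: (
                np.array([li for li, _ in pairs], dtype=np.int64),
                np.array([c for _, c in pairs], dtype=np.int64),
            )
            for d, pairs in per_device.items()
        }
        out.append(
            ReportSources(
                spec=spec,
                publisher_kind=_PUBLISHER_OF_VALUE[spec.value],
                per_device=packed,
                sorted_ids=sorted_ids,
            )
        )
    return out


def _fmt(v: float) -> str:
    return repr(float(v))


class Reporter:
    """Single per-machine reporter aggregating all report specs."""

    def __init__(
        self,
        reports: Sequence[ReportSpec],
        sources: Sequence[ReportSources],
        network_of_local: Sequence[np.ndarray],
        header: Mapping[str, object],
    ):
        self.sources = list(sources)
        self.network_of_local = network_of_local
        self._lines: dict[str, list[str]] = {}
        meta = [f"# {k}={v}" for k, v in header.items()]
        for src in self.sources:
            lines = list(meta)
            if src.spec.value == "spike":
                lines.append("step,neuron")
            elif src.spec.value == "spike_count":
                lines.append("step,count")
            else:
                lines.append(
                    "step," + ",".join(f"n{i}" for i in src.sorted_ids)
                )
            self._lines[src.spec.name] = lines

    def needed_publishers(self) -> list[tuple[str, int]]:
        need = {
            (src.publisher_kind, d)
            for src in self.sources
            for d in src.per_device
        }
        return sorted(need)

    def collect(self, t: int, payloads: Mapping[str, object]) -> None:
        """Extract one step's values from the acquired buffers."""
        for src in self.sources:
            if t % src.spec.cadence:
                continue
            lines = self._lines[src.spec.name]
            if src.spec.value == "spike":
                fired_ids: list[int] = []
                for d, (local, _cols) in sorted(src.per_device.items()):
                    _voltage, fires = payloads[f"neuron_out[{d}]"]
                    mask = fires.to_bool_array()[local]
                    fired_ids.extend(
                        int(self.network_of_local[d][li])
                        for li in local[mask]
                    )
                for nid in sorted(fired_ids):
                    lines.append(f"{t},{nid}")
            elif src.spec.value == "spike_count":
                count = 0
                for d, (local, _cols) in sorted(src.per_device.items()):
                    _voltage, fires = payloads[f"neuron_out[{d}]"]
                    count += int(fires.to_bool_array()[local].sum())
                lines.append(f"{t},{count}")
            else:
                row = np.empty(src.sorted_ids.size, dtype=np.float64)
                for d, (local, cols) in sorted(src.per_device.items()):
                    payload = payloads[f"{src.publisher_kind}[{d}]"]
                    if src.publisher_kind == "neuron_out":
                        voltage, _fires = payload
                        vals = voltage[local]
                    elif src.publisher_kind == "input_current":
                        current, _cv, _cs = payload
                        vals = current[local]
                    else:
                        vals = payload[local]
                    row[cols] = vals
                lines.append(f"{t}," + ",".join(_fmt(v) for v in row))

    def finalize(self) -> dict[str, str]:
        return {name: "\n".join(lines) + "\n" for name, lines in self._lines.items()}
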