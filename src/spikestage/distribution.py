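"""Load balancing of simulation elements across logical compute devices.

Each device gets a relative power rating (clock rate x core count).  Each
neuron's computational cost is estimated as its number of afferent
synapses, since synapses dominate the work by orders of magnitude.
Neurons are then handed out greedily in decreasing cost order, each going
to the device whose current load ratio (assigned cost / power) is lowest.
Finally every synapse and stimulus is colocated with the device of its
postsynaptic / target neuron, so membrane voltages and synaptic currents
stay device-local; only the one-bit spike state ever crosses devices.

Ties (equal load ratios; equal neuron costs) are broken by device list
order and ascending neuron ID respectively, making the assignment fully
deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence, TextIO

from .scopes import ConfigurationError

__all__ = [
    "DeviceSpec",
    "CostedNeuron",
    "Placement",
    "rate_device",
    "estimate_costs",
    "distribute",
    "colocate",
]


def rate_device(clock_rate_mhz: float, cores: int) -> float:
    """Relative computational power of a device: clock rate times core count."""
    if clock_rate_mhz <= 0:
        raise ConfigurationError(f"clock rate must be positive, got {clock_rate_mhz}")
    if cores < 1:
        raise ConfigurationError(f"core count must be >= 1, got {cores}")
    return clock_rate_mhz * cores


@dataclass(frozen=True)
class DeviceSpec:
    """A logical compute unit.  ``kind`` is a descriptive label only."""

    name: str
    clock_rate_mhz: float
    cores: int
    kind: str = "cpu"

    @property
    def power(self) -> float:
        return rate_device(self.clock_rate_mhz, self.cores)


@dataclass(frozen=True)
class CostedNeuron:
    """A neuron and its cost estimate: the count of synapses targeting it."""

    neuron_id: int
    cost: int


@dataclass
class Placement:
    """Element-to-device assignment produced by the balancer.

    ``device_neurons[d]`` preserves assignment order; synapses and stimuli
    always map to the device of their postsynaptic / target neuron.
    """

    neuron_device: dict[int, int]
    device_neurons: list[list[int]]
    synapse_device: dict[int, int] = field(default_factory=dict)
    stimulus_device: dict[int, int] = field(default_factory=dict)
    assignment_log: list[tuple[int, int, float]] = field(default_factory=list)
    # (neuron_id, device, load ratio at the moment of choice)

    def write_csv(self, fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(["kind", "global_id", "device"])
        for nid in sorted(self.neuron_device):
            w.writerow(["neuron", nid, self.neuron_device[nid]])
        for sid in sorted(self.synapse_device):
            w.writerow(["synapse", sid, self.synapse_device[sid]])
        for tid in sorted(self.stimulus_device):
            w.writerow(["stimulus", tid, self.stimulus_device[tid]])


def estimate_costs(
    n_neurons: int, synapse_post: Sequence[int]
) -> list[CostedNeuron]:
    """Cost each neuron by its afferent synapse count.

    ``synapse_post[s]`` is the postsynaptic neuron of synapse ``s``.  Costs
    sum to the total synapse count; neurons with no afferents cost 0.
    """
    counts = [0] * n_neurons
    for post in synapse_post:
        counts[post] += 1
    return [CostedNeuron(i, c) for i, c in enumerate(counts)]


def distribute(
    costs: Sequence[CostedNeuron], devices: Sequence[DeviceSpec]
) -> Placement:
    """Greedy balanced assignment of neurons to devices.

    Neurons are visited in decreasing cost (ascending ID among equal costs);
    each goes to the device with the smallest current load ratio
    ``assigned_cost / power``, earliest device winning ties.
    """
    if not devices:
        raise ConfigurationError("at least one device is required")
    powers = [d.power for d in devices]
    loads = [0.0] * len(devices)
    order = sorted(costs, key=lambda cn: (-cn.cost, cn.neuron_id))
    placement = Placement(
        neuron_device={}, device_neurons=[[] for _ in devices]
    )
    for cn in order:
        ratios = [loads[d] / powers[d] for d in range(len(devices))]
        best = min(range(len(devices)), key=lambda d: ratios[d])
        placement.neuron_device[cn.neuron_id] = best
        placement.device_neurons[best].append(cn.neuron_id)
        placement.assignment_log.append((cn.neuron_id, best, ratios[best]))
        loads[best] += cn.cost
    return placement


def colocate(
    placement: Placement,
    synapse_post: Sequence[int],
    stimulus_target: Sequence[int],
    compartment_groups: Sequence[Sequence[int]] = (),
) -> Placement:
    """Map synapses and stimuli onto their target neurons' devices.

    ``compartment_groups`` lists neuron-ID groups (the compartments of one
    multi-compartment cell) that must share a device; each group is pulled
    onto the device of its first member so cross-compartment couplings stay
    device-local.
    """
    for group in compartment_groups:
        if not group:
            continue
        home = placement.neuron_device[group[0]]
        for nid in group[1:]:
            old = placement.neuron_device[nid]
            if old != home:
                placement.neuron_device[nid] = home
                placement.device_neurons[old].remove(nid)
                placement.device_neurons[home].append(nid)
    for sid, post in enumerate(synapse_post):
        if post not in placement.neuron_device:
            raise ConfigurationError(
                f"synapse {sid} targets unknown neuron {post}"
            )
        placement.synapse_device[sid] = placement.neuron_device[post]
    for tid, target in enumerate(stimulus_target):
        if target not in placement.neuron_device:
            raise ConfigurationError(
                f"stimulus {tid} targets unknown neuron {target}"
            )
        placement.stimulus_device[tid] = placement.neuron_device[target]
    return placement
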