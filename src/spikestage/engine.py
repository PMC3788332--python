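"""The staged simulation engine.

Each time-step flows through five per-device stages plus a global
exchanger, mirroring the dataflow of a distributed cluster inside one
process:

1. **input update** — total stimulus current and voltage-clamp selection
   per device neuron; depends on no other stage, so it free-runs up to
   its buffer limit.
2. **synapse update** — consumes the firing-table row for the step,
   advances waveform events, produces the synaptic current per device
   neuron.
3. **neuron update** — consumes input + synaptic current, produces the
   membrane voltage array and the device's spike bit vector.
4. **vector exchange** — gathers every device's local fire vector into
   the layout-ordered global vector (an in-process stand-in for the
   cluster broadcast) and hands it back to every device.
5. **firing-table update** — for each synapse whose presynaptic global
   bit is set, sets a bit in the row ``delay`` steps ahead; rows up to
   ``t + N_min`` (the minimum local delay) become publishable, which is
   exactly how far devices may run ahead of each other.

Reporters subscribe to published buffers and write CSV sinks.

Stages communicate only through bounded publisher–subscriber buffer
pools: a publisher with all its buffers outstanding cannot run, so no
stage gets unboundedly ahead.  The scheduler here is serial and
deterministic — concurrency is an optimisation the data contract
permits, not a semantic — and an optional audit log records every
acquire/publish/release for contract checks.

Determinism and partition invariance: all per-neuron current sums are
accumulated in a fixed order (ascending arrival step, then ascending
network source ID), so spike rasters and voltage traces are bit-identical
for any device partitioning of the same network and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import neurons as nm
from .distribution import DeviceSpec, Placement, colocate, distribute, estimate_costs
from .network import Network
from .reports import Reporter, resolve_sources
from .scopes import (
    ConfigurationError,
    IDLayout,
    Scope,
    SpikeBitVector,
    allocate_layout,
)
from .synapses import (
    StimulusInstance,
    SynapseGroup,
    WaveformEventList,
    input_update,
    synapse_update,
)

__all__ = ["Engine", "RunResult", "run", "vector_exchange"]

MODEL_ORDER = ("izh", "lif")


# --------------------------------------------------------------------------
# publisher-subscriber plumbing
# --------------------------------------------------------------------------


@dataclass
class DataBuffer:
    payload: object
    time_step: int
    publisher: str
    refs: int


class Publisher:
    """A stage's bounded pool of publishable, time-stamped buffers.

    ``capacity`` limits outstanding (published but not fully released)
    buffers; a buffer returns to the pool only when every subscriber has
    released it.  Publishing with a full pool is a contract violation —
    the scheduler must not run a stage that cannot publish.
    """

    def __init__(self, name: str, capacity: int, audit: Optional[list] = None):
        self.name = name
        self.capacity = capacity
        self.subscribers: list[str] = []
        self.buffers: dict[int, DataBuffer] = {}
        self.audit = audit

    def subscribe(self, stage_name: str) -> None:
        self.subscribers.append(stage_name)

    def can_publish(self) -> bool:
        return len(self.buffers) < self.capacity

    def publish(self, step: int, payload: object) -> None:
        if not self.can_publish():
            raise RuntimeError(
                f"publisher {self.name} pool exhausted at step {step}"
            )
        if step in self.buffers:
            raise RuntimeError(f"publisher {self.name} republished step {step}")
        if self.audit is not None:
            self.audit.append((self.name, step, "publish", self.name, step))
        if self.subscribers:
            self.buffers[step] = DataBuffer(payload, step, self.name, len(self.subscribers))
        # with no subscribers the buffer is immediately recycled

    def available(self, step: int) -> bool:
        return step in self.buffers

    def acquire(self, step: int, consumer: str) -> object:
        buf = self.buffers[step]
        if buf.time_step != step:
            raise RuntimeError("buffer stamp mismatch")
        if self.audit is not None:
            self.audit.append((consumer, step, "acquire", self.name, buf.time_step))
        return buf.payload

    def release(self, step: int, consumer: str) -> None:
        buf = self.buffers.get(step)
        if buf is None or buf.refs <= 0:
            raise RuntimeError(
                f"double release of {self.name}@{step} by {consumer}"
            )
        buf.refs -= 1
        if self.audit is not None:
            self.audit.append((consumer, step, "release", self.name, step))
        if buf.refs == 0:
            del self.buffers[step]


class Stage:
    """Base class: one unit of schedulable per-step work."""

    def __init__(self, name: str, total_steps: int):
        self.name = name
        self.total_steps = total_steps
        self.step = 0

    @property
    def done(self) -> bool:
        return self.step >= self.total_steps

    def ready(self) -> bool:
        raise NotImplementedError

    def run_one(self) -> None:
        raise NotImplementedError


# --------------------------------------------------------------------------
# per-device runtime structures
# --------------------------------------------------------------------------


@dataclass
class DeviceRuntime:
    """Everything one logical device owns: populations, synapses, stimuli."""

    index: int
    layout: IDLayout  # device-scope neuron layout (padded per plugin)
    n_bits: int  # padded device bit length
    local_of_network: dict[int, int]
    network_of_local: np.ndarray  # padded; -1 in padding holes
    populations: list[tuple[str, int, object]]  # (model, base, population)
    syn_groups: list[SynapseGroup]  # one per psg-template plugin
    syn_layout: IDLayout
    syn_pre_global: np.ndarray  # per populated synapse bit position
    syn_delay: np.ndarray
    syn_positions: np.ndarray  # bit positions in the synapse layout
    stimuli: list[StimulusInstance]
    n_min_delay: int
    row_count: int


def vector_exchange(
    local_vectors: Sequence[SpikeBitVector],
    device_bases: Sequence[int],
    total_bits: int,
    time_step: int,
) -> SpikeBitVector:
    """Concatenate device fire vectors into the global vector.

    Device padded lengths are word multiples, so the global vector is a
    word-level concatenation in layout order; bit ``base_d + i`` of the
    result equals bit ``i`` of device ``d``'s vector.
    """
    out = SpikeBitVector.zeros(total_bits, time_step)
    for base, vec in zip(device_bases, local_vectors):
        if vec.time_step != time_step:
            raise RuntimeError(
                f"exchange at step {time_step} received vector for {vec.time_step}"
            )
        w0 = base // 32
        out.words[w0 : w0 + vec.words.size] = vec.words
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


class InputStage(Stage):
    def __init__(self, dev: DeviceRuntime, pub: Publisher, total: int):
        super().__init__(f"input[{dev.index}]", total)
        self.dev = dev
        self.pub = pub

    def ready(self) -> bool:
        return self.pub.can_publish()

    def run_one(self) -> None:
        t = self.step
        current, clamp_v, clamp_sel = input_update(
            self.dev.stimuli, t, self.dev.n_bits
        )
        self.pub.publish(t, (current, clamp_v, clamp_sel))
        self.step += 1


class SynapseStage(Stage):
    def __init__(self, dev: DeviceRuntime, row_pub: Publisher, pub: Publisher, total: int):
        super().__init__(f"synapse[{dev.index}]", total)
        self.dev = dev
        self.row_pub = row_pub
        self.pub = pub
        # double-buffered event lists, one pair per synapse plugin
        self.events = [WaveformEventList() for _ in dev.syn_groups]

    def ready(self) -> bool:
        return self.row_pub.available(self.step) and self.pub.can_publish()

    def run_one(self) -> None:
        t = self.step
        row: SpikeBitVector = self.row_pub.acquire(t, self.name)
        total = np.zeros(self.dev.n_bits, dtype=np.float64)
        fired_positions = row.to_indices()
        for gi, group in enumerate(self.dev.syn_groups):
            base = self.dev.syn_layout.partitions[gi].base
            count = self.dev.syn_layout.partitions[gi].count
            in_group = fired_positions[
                (fired_positions >= base) & (fired_positions < base + count)
            ]
            current, self.events[gi] = synapse_update(
                in_group - base, self.events[gi], group, self.dev.n_bits
            )
            total += current
        self.row_pub.release(t, self.name)
        self.pub.publish(t, total)
        self.step += 1


class NeuronStage(Stage):
    def __init__(
        self,
        dev: DeviceRuntime,
        in_pub: Publisher,
        syn_pub: Publisher,
        pub: Publisher,
        total: int,
    ):
        super().__init__(f"neuron[{dev.index}]", total)
        self.dev = dev
        self.in_pub = in_pub
        self.syn_pub = syn_pub
        self.pub = pub

    def ready(self) -> bool:
        return (
            self.in_pub.available(self.step)
            and self.syn_pub.available(self.step)
            and self.pub.can_publish()
        )

    def run_one(self) -> None:
        t = self.step
        current, clamp_v, clamp_sel = self.in_pub.acquire(t, self.name)
        syn_current = self.syn_pub.acquire(t, self.name)
        voltage = np.zeros(self.dev.n_bits, dtype=np.float64)
        fires = SpikeBitVector.zeros(self.dev.n_bits, t)
        for model, base, pop in self.dev.populations:
            n = len(pop)
            sl = slice(base, base + n)
            if model == "izh":
                total_i = current[sl] + syn_current[sl]
                u_pre = pop.u.copy()
                v_pre = pop.v.copy()
                try:
                    reported, fired = pop.step(total_i)
                except nm.NumericError as exc:
                    raise nm.NumericError(f"step {t}, device {self.dev.index}: {exc}")
                sel = clamp_sel[sl]
                if sel.any():
                    # clamp wins: hold the commanded voltage, freeze the
                    # recovery variable, suppress firing
                    reported = np.where(sel, clamp_v[sl], reported)
                    pop.v = np.where(sel, clamp_v[sl], pop.v)
                    pop.u = np.where(sel, u_pre, pop.u)
                    fired = fired & ~sel
                voltage[sl] = reported
            else:
                try:
                    reported, fired = pop.step(
                        syn_current[sl], current[sl], clamp_v[sl], clamp_sel[sl]
                    )
                except nm.NumericError as exc:
                    raise nm.NumericError(f"step {t}, device {self.dev.index}: {exc}")
                voltage[sl] = reported
            fires.set_from_indices(base + np.nonzero(fired)[0])
        self.in_pub.release(t, self.name)
        self.syn_pub.release(t, self.name)
        self.pub.publish(t, (voltage, fires))
        self.step += 1


class ExchangeStage(Stage):
    """In-process gather/broadcast of per-device fire vectors."""

    def __init__(
        self,
        neuron_pubs: list[Publisher],
        device_bases: list[int],
        total_bits: int,
        pub: Publisher,
        total: int,
    ):
        super().__init__("exchange", total)
        self.neuron_pubs = neuron_pubs
        self.device_bases = device_bases
        self.total_bits = total_bits
        self.pub = pub

    def ready(self) -> bool:
        return (
            all(p.available(self.step) for p in self.neuron_pubs)
            and self.pub.can_publish()
        )

    def run_one(self) -> None:
        t = self.step
        locals_ = []
        for p in self.neuron_pubs:
            _voltage, fires = p.acquire(t, self.name)
            locals_.append(fires)
        global_vec = vector_exchange(
            locals_, self.device_bases, self.total_bits, t
        )
        for p in self.neuron_pubs:
            p.release(t, self.name)
        self.pub.publish(t, global_vec)
        self.step += 1


class FiringTableStage(Stage):
    """Delay-indexed synaptic firing table for one device.

    Logically a ring of ``max local delay + 1`` bit-vector rows; a spike at
    step ``t`` with delay ``d`` sets a bit in the row for step ``t + d``.
    After processing the global vector for ``t``, the row for ``t + N_min``
    is complete and published (``N_min`` = minimum local delay); rows
    ``0 .. N_min-1``, which no spike can reach, are pre-published as zeros
    at start so data begins flowing through the pipeline.
    """

    def __init__(self, dev: DeviceRuntime, glob_pub: Publisher, pub: Publisher, total: int):
        super().__init__(f"firing_table[{dev.index}]", total)
        self.dev = dev
        self.glob_pub = glob_pub
        self.pub = pub
        self.pending: dict[int, SpikeBitVector] = {}
        self.primed = False

    def prime(self) -> None:
        for s in range(min(self.dev.n_min_delay, self.total_steps)):
            self.pub.publish(s, SpikeBitVector.zeros(self.dev.syn_layout.total_bits, s))
        self.primed = True

    def ready(self) -> bool:
        return self.glob_pub.available(self.step) and self.pub.can_publish()

    def run_one(self) -> None:
        t = self.step
        global_vec: SpikeBitVector = self.glob_pub.acquire(t, self.name)
        if self.dev.syn_pre_global.size:
            pre_fired = global_vec.to_bool_array()[self.dev.syn_pre_global]
            idx = np.nonzero(pre_fired)[0]
            if idx.size:
                arrive = t + self.dev.syn_delay[idx]
                if int(self.dev.syn_delay.max(initial=0)) >= self.dev.row_count:
                    raise RuntimeError("synapse delay exceeds firing-table rows")
                for s in np.unique(arrive):
                    row = self.pending.get(int(s))
                    if row is None:
                        row = SpikeBitVector.zeros(
                            self.dev.syn_layout.total_bits, int(s)
                        )
                        self.pending[int(s)] = row
                    row.set_from_indices(
                        self.dev.syn_positions[idx[arrive == s]]
                    )
        self.glob_pub.release(t, self.name)
        publish_step = t + self.dev.n_min_delay
        if publish_step < self.total_steps:
            row = self.pending.pop(
                publish_step,
                SpikeBitVector.zeros(self.dev.syn_layout.total_bits, publish_step),
            )
            row.time_step = publish_step
            self.pub.publish(publish_step, row)
        self.step += 1


class ReporterStage(Stage):
    """The machine's single reporter: consumes subscriptions, feeds sinks."""

    def __init__(self, reporter: Reporter, pubs: dict[str, Publisher], total: int):
        super().__init__("reporter", total)
        self.reporter = reporter
        self.pubs = pubs  # publisher name -> Publisher (its subscriptions)

    def ready(self) -> bool:
        return all(p.available(self.step) for p in self.pubs.values())

    def run_one(self) -> None:
        t = self.step
        payloads = {
            name: p.acquire(t, self.name) for name, p in self.pubs.items()
        }
        self.reporter.collect(t, payloads)
        for p in self.pubs.values():
            p.release(t, self.name)
        self.step += 1


# --------------------------------------------------------------------------
# the engine
# --------------------------------------------------------------------------


@dataclass
class RunResult:
    """Outputs of one run: report sink texts plus build artefacts."""

    reports: dict[str, str]
    placement: Placement
    global_layout: IDLayout
    device_layouts: list[IDLayout]
    audit: Optional[list] = None
    files: dict[str, str] = field(default_factory=dict)

    def raster(self, name: str) -> np.ndarray:
        """(step, network ID) pairs of a spike-raster report, as an array."""
        rows = [
            line.split(",")
            for line in self.reports[name].splitlines()
            if line and not line.startswith("#") and not line.startswith("step")
        ]
        if not rows:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(rows, dtype=np.int64)


class Engine:
    """Builds the staged dataflow for a network/device roster and runs it."""

    def __init__(
        self,
        network: Network,
        devices: Sequence[DeviceSpec],
        dt: float = 1.0,
        seed: Optional[int] = None,
        buffer_capacity: int = 2,
        audit: bool = False,
    ):
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        self.network = network
        self.devices = list(devices)
        self.dt = float(dt)
        self.seed = network.seed if seed is None else int(seed)
        self.buffer_capacity = int(buffer_capacity)
        self.audit: Optional[list] = [] if audit else None
        self._build_placement()
        self._build_runtimes()

    # -- construction ------------------------------------------------------

    def _build_placement(self) -> None:
        net = self.network
        costs = estimate_costs(net.n_elements, net.syn_post)
        placement = distribute(costs, self.devices)
        comp_groups: dict[int, list[int]] = {}
        for el in net.elements:
            comp_groups.setdefault(el.cell_id, []).append(el.network_id)
        placement = colocate(
            placement,
            net.syn_post,
            [s.target for s in net.stimuli],
            [g for g in comp_groups.values() if len(g) > 1],
        )
        self.placement = placement

    def _build_runtimes(self) -> None:
        net = self.network
        n_dev = len(self.devices)
        self.runtimes: list[DeviceRuntime] = []

        # neuron layouts: per device, plugin blocks in fixed model order
        device_parts: list[list[tuple[str, int]]] = []
        members: list[dict[str, list[int]]] = []
        for d in range(n_dev):
            by_model = {m: [] for m in MODEL_ORDER}
            for nid in sorted(self.placement.device_neurons[d]):
                by_model[net.elements[nid].model].append(nid)
            members.append(by_model)
            device_parts.append(
                [(f"dev{d}/{m}", len(by_model[m])) for m in MODEL_ORDER]
            )
        global_parts = [p for parts in device_parts for p in parts]
        self.global_layout = allocate_layout(global_parts)
        self.device_layouts = [allocate_layout(parts) for parts in device_parts]
        self.device_bases = []
        offset = 0
        for d in range(n_dev):
            self.device_bases.append(offset)
            offset += self.device_layouts[d].total_bits

        global_of_network = np.full(net.n_elements, -1, dtype=np.int64)
        local_maps: list[dict[int, int]] = []
        for d in range(n_dev):
            layout = self.device_layouts[d]
            local_of_network: dict[int, int] = {}
            for part, model in zip(layout.partitions, MODEL_ORDER):
                for k, nid in enumerate(members[d][model]):
                    local = part.base + k
                    local_of_network[nid] = local
                    global_of_network[nid] = self.device_bases[d] + local
            local_maps.append(local_of_network)
        self.global_of_network = global_of_network

        # synapses per device, grouped by psg template (one plugin per template)
        syn_by_dev: list[list[int]] = [[] for _ in range(n_dev)]
        for sid in range(net.n_synapses):
            syn_by_dev[self.placement.synapse_device[sid]].append(sid)

        stim_by_dev: list[list[int]] = [[] for _ in range(n_dev)]
        for tid, _spec in enumerate(net.stimuli):
            stim_by_dev[self.placement.stimulus_device[tid]].append(tid)

        for d in range(n_dev):
            layout = self.device_layouts[d]
            local_of_network = local_maps[d]
            n_bits = layout.total_bits  # zero for a device with no neurons

            network_of_local = np.full(n_bits, -1, dtype=np.int64)
            for nid, local in local_of_network.items():
                network_of_local[local] = nid

            pops: list[tuple[str, int, object]] = []
            for part, model in zip(layout.partitions, MODEL_ORDER):
                ids = members[d][model]
                if not ids:
                    continue
                if model == "izh":
                    pop = nm.IzhPopulation(
                        [net.elements[i].params for i in ids], dt=self.dt
                    )
                else:
                    couplings = []
                    for i in ids:
                        el = net.elements[i]
                        local_coup = []
                        for other_nid, g in el.couplings:
                            other_local = local_of_network[other_nid] - part.base
                            local_coup.append((other_local, g))
                        couplings.append(local_coup)
                    pop = nm.LIFPopulation(
                        [net.elements[i].params for i in ids],
                        couplings=couplings,
                        dt=self.dt,
                    )
                pops.append((model, part.base, pop))

            # synapse plugins: one per template id, ascending; synapses
            # ordered by ascending network ID inside each plugin
            sids = syn_by_dev[d]
            tids = sorted({int(net.syn_template_id[s]) for s in sids})
            parts = []
            groups: list[SynapseGroup] = []
            per_plugin: list[list[int]] = []
            for tid in tids:
                plugin_sids = sorted(
                    s for s in sids if int(net.syn_template_id[s]) == tid
                )
                per_plugin.append(plugin_sids)
                parts.append((f"dev{d}/psg{tid}", len(plugin_sids)))
            syn_layout = allocate_layout(parts)
            pos_l, preg_l, delay_l = [], [], []
            for part, plugin_sids, tid in zip(syn_layout.partitions, per_plugin, tids):
                arr = np.array(plugin_sids, dtype=np.int64)
                groups.append(
                    SynapseGroup(
                        network_ids=arr,
                        pre_global=global_of_network[net.syn_pre[arr]]
                        if arr.size
                        else np.empty(0, dtype=np.int64),
                        post_local=np.array(
                            [local_of_network[int(net.syn_post[s])] for s in plugin_sids],
                            dtype=np.int64,
                        ),
                        weight=net.syn_weight[arr],
                        delay=net.syn_delay[arr],
                        template=net.templates[tid],
                    )
                )
                pos_l.append(part.base + np.arange(arr.size, dtype=np.int64))
                preg_l.append(global_of_network[net.syn_pre[arr]] if arr.size else np.empty(0, dtype=np.int64))
                delay_l.append(net.syn_delay[arr])
            syn_positions = (
                np.concatenate(pos_l) if pos_l else np.empty(0, dtype=np.int64)
            )
            syn_pre_global = (
                np.concatenate(preg_l) if preg_l else np.empty(0, dtype=np.int64)
            )
            syn_delay = (
                np.concatenate(delay_l) if delay_l else np.empty(0, dtype=np.int64)
            )

            stimuli = [
                StimulusInstance(
                    net.stimuli[tid],
                    local_of_network[net.stimuli[tid].target],
                    self.seed,
                    tid,
                )
                for tid in stim_by_dev[d]
            ]

            n_min = int(syn_delay.min()) if syn_delay.size else 1
            row_count = (int(syn_delay.max()) + 1) if syn_delay.size else 1
            self.runtimes.append(
                DeviceRuntime(
                    index=d,
                    layout=layout,
                    n_bits=n_bits,
                    local_of_network=local_of_network,
                    network_of_local=network_of_local,
                    populations=pops,
                    syn_groups=groups,
                    syn_layout=syn_layout,
                    syn_pre_global=syn_pre_global,
                    syn_delay=syn_delay,
                    syn_positions=syn_positions,
                    stimuli=stimuli,
                    n_min_delay=n_min,
                    row_count=row_count,
                )
            )

    def scope_layouts(self, device: int) -> dict[Scope, IDLayout]:
        """Neuron ID layouts for translate(): plugin/device/machine/global.

        The machine scope hosts all devices in this single-process engine,
        so it coincides with the global scope.
        """
        return {
            Scope.DEVICE: self.device_layouts[device],
            Scope.MACHINE: self.global_layout,
            Scope.GLOBAL: self.global_layout,
        }

    # -- execution ---------------------------------------------------------

    def run(
        self,
        duration_ms: float,
        out_dir: Optional[str] = None,
    ) -> RunResult:
        total = int(round(duration_ms / self.dt))
        net = self.network
        B = self.buffer_capacity
        audit = self.audit

        in_pubs = [Publisher(f"input_current[{d}]", B, audit) for d in range(len(self.runtimes))]
        syn_pubs = [Publisher(f"syn_current[{d}]", B, audit) for d in range(len(self.runtimes))]
        neu_pubs = [Publisher(f"neuron_out[{d}]", B, audit) for d in range(len(self.runtimes))]
        glob_pub = Publisher("global_fires", B, audit)
        row_pubs = [
            Publisher(f"fire_rows[{d}]", max(rt.row_count, rt.n_min_delay + 1), audit)
            for d, rt in enumerate(self.runtimes)
        ]

        stages: list[Stage] = []
        for d, rt in enumerate(self.runtimes):
            stages.append(InputStage(rt, in_pubs[d], total))
            stages.append(SynapseStage(rt, row_pubs[d], syn_pubs[d], total))
            stages.append(NeuronStage(rt, in_pubs[d], syn_pubs[d], neu_pubs[d], total))
        exchange = ExchangeStage(
            neu_pubs, self.device_bases, self.global_layout.total_bits,
            glob_pub, total,
        )
        stages.append(exchange)
        tables = []
        for d, rt in enumerate(self.runtimes):
            ft = FiringTableStage(rt, glob_pub, row_pubs[d], total)
            tables.append(ft)
            stages.append(ft)

        # wire subscriptions (refcounting needs subscriber counts up front)
        for d in range(len(self.runtimes)):
            in_pubs[d].subscribe(f"neuron[{d}]")
            syn_pubs[d].subscribe(f"neuron[{d}]")
            neu_pubs[d].subscribe("exchange")
            glob_pub.subscribe(f"firing_table[{d}]")
            row_pubs[d].subscribe(f"synapse[{d}]")

        reporter = None
        if net.reports:
            sources = resolve_sources(
                net.reports,
                {nid: self.placement.neuron_device[nid] for nid in range(net.n_elements)},
                [rt.local_of_network for rt in self.runtimes],
            )
            reporter = Reporter(
                net.reports,
                sources,
                [rt.network_of_local for rt in self.runtimes],
                header={
                    "network": net.content_hash(),
                    "seed": self.seed,
                    "dt": self.dt,
                },
            )
            sub_pubs: dict[str, Publisher] = {}
            for pub_name in reporter.needed_publishers():
                kind, dev = pub_name
                pub = {"input_current": in_pubs, "syn_current": syn_pubs,
                       "neuron_out": neu_pubs}[kind][dev]
                key = f"{kind}[{dev}]"
                pub.subscribe("reporter")
                sub_pubs[key] = pub
            stages.append(ReporterStage(reporter, sub_pubs, total))

        for ft in tables:
            ft.prime()

        # serial deterministic scheduler honouring the pub-sub contract
        while True:
            progressed = False
            for st in stages:
                while not st.done and st.ready():
                    st.run_one()
                    progressed = True
            if all(st.done for st in stages):
                break
            if not progressed:
                status = ", ".join(f"{st.name}@{st.step}" for st in stages if not st.done)
                raise RuntimeError(f"pipeline deadlock; blocked stages: {status}")

        report_texts = reporter.finalize() if reporter else {}
        files: dict[str, str] = {}
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            for spec in net.reports:
                if spec.sink != "memory":
                    path = os.path.join(out_dir, spec.sink)
                    with open(path, "w", encoding="utf-8", newline="\n") as fh:
                        fh.write(report_texts[spec.name])
                    files[spec.name] = path
        return RunResult(
            reports=report_texts,
            placement=self.placement,
            global_layout=self.global_layout,
            device_layouts=self.device_layouts,
            audit=audit,
            files=files,
        )


def run(
    network: Network,
    devices: Sequence[DeviceSpec],
    duration_ms: float,
    dt: float = 1.0,
    seed: Optional[int] = None,
    out_dir: Optional[str] = None,
    buffer_capacity: int = 2,
    audit: bool = False,
) -> RunResult:
    """Build the staged dataflow and simulate ``duration_ms / dt`` steps.

    Identical (network, devices, seed) triples produce bit-identical
    report sinks regardless of scheduling or device count.
    """
    eng = Engine(
        network,
        devices,
        dt=dt,
        seed=seed,
        buffer_capacity=buffer_capacity,
        audit=audit,
    )
    return eng.run(duration_ms, out_dir=out_dir)
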