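"""Synapse plugins (delayed waveform currents) and stimulus plugins.

A presynaptic spike does not deliver a single impulse: after the synapse's
integer delay it starts playback of a postsynaptic current waveform — the
``psg_template``, a unit-normalised amplitude sequence scaled by the
synapse weight (nA, signed for inhibition).  Each arrival pushes a
*waveform event* (a playback iterator) onto the plugin's event list; all
live events contribute ``weight * template[offset]`` to their
postsynaptic neuron's current and overlapping events sum linearly.  Event
lists are double-buffered: the update consumes the previous step's list
and publishes the list of still-live events for the next step.

Stimuli either inject current (adding across co-targeted stimuli) or
clamp the membrane voltage; a bit vector selects the clamped neurons.
The input stage depends on no other stage, so it can run ahead of the
rest of the pipeline up to its buffer limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .rng import child_rng
from .scopes import ConfigurationError

__all__ = [
    "default_psg_template",
    "SynapseGroup",
    "WaveformEventList",
    "StimulusSpec",
    "input_update",
    "synapse_update",
]


def default_psg_template(
    rise_ms: float = 1.0, decay_ms: float = 3.0, dt: float = 1.0
) -> np.ndarray:
    """Peak-normalised discretised double-exponential current waveform.

    ``A (exp(-t/decay) - exp(-t/rise))`` sampled every ``dt`` ms starting at
    the arrival step, truncated where the tail falls below 1% of peak.
    """
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise ConfigurationError("need 0 < rise < decay for the psg template")
    t_peak = (
        rise_ms * decay_ms / (decay_ms - rise_ms) * math.log(decay_ms / rise_ms)
    )
    t_end = t_peak + decay_ms * math.log(100.0)
    t = np.arange(dt, t_end + dt, dt)  # first sample one dt after arrival onset
    wave = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    wave /= wave.max()
    return wave[wave >= 0.01]


@dataclass
class SynapseGroup:
    """All synapses managed by one synapse plugin on one device.

    Arrays are parallel, ordered by ascending network synapse ID (that
    fixed order is what makes per-neuron current sums independent of the
    device partitioning).  ``post_local`` holds device-level neuron indices;
    ``pre_global`` holds global-scope neuron bit positions for the firing
    table.  ``max |template| = 1``: the weight carries the magnitude.
    """

    network_ids: np.ndarray
    pre_global: np.ndarray
    post_local: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    template: np.ndarray

    def __post_init__(self) -> None:
        if self.template.size == 0:
            raise ConfigurationError("psg template must be non-empty")
        peak = np.abs(self.template).max()
        if not np.isclose(peak, 1.0):
            raise ConfigurationError(
                f"psg template must be peak-normalised (max |amp| = 1, got {peak})"
            )
        if self.delay.size and self.delay.min() < 1:
            raise ConfigurationError("synaptic delays must be >= 1 step")

    def __len__(self) -> int:
        return self.network_ids.size


@dataclass
class WaveformEventList:
    """Live playback events: parallel arrays of synapse index and offset.

    Ordered oldest-first, ties by ascending plugin-local synapse index;
    ``0 <= offset < len(template)`` always holds.
    """

    syn_index: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    offset: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __len__(self) -> int:
        return self.syn_index.size


def synapse_update(
    fire_row_indices: np.ndarray,
    events_prev: WaveformEventList,
    group: SynapseGroup,
    n_local_neurons: int,
) -> tuple[np.ndarray, WaveformEventList]:
    """One synapse-stage step: consume a firing-table row, emit currents.

    ``fire_row_indices`` are plugin-local indices of synapses whose delayed
    presynaptic firing arrives this step; each pushes a fresh event at
    template offset 0.  All live events then contribute
    ``weight * template[offset]``; offsets advance and exhausted events are
    dropped.  Returns the device-neuron current vector and the double
    buffer's next event list.

    Contributions are accumulated oldest-event-first then ascending synapse
    index (a sequential ``bincount``), so each neuron's floating-point sum
    is independent of how neurons were partitioned across devices.
    """
    new = np.asarray(fire_row_indices, dtype=np.int64)
    syn = np.concatenate([events_prev.syn_index, new])
    off = np.concatenate([events_prev.offset, np.zeros(new.size, dtype=np.int64)])
    if syn.size:
        contrib = group.weight[syn] * group.template[off]
        current = np.bincount(
            group.post_local[syn], weights=contrib, minlength=n_local_neurons
        )
    else:
        current = np.zeros(n_local_neurons, dtype=np.float64)
    nxt = off + 1
    live = nxt < group.template.size
    return current, WaveformEventList(syn[live], nxt[live])


@dataclass(frozen=True)
class StimulusSpec:
    """External input to one neuron over a half-open step window.

    ``kind`` is ``"current"`` (amplitude in nA, additive across stimuli) or
    ``"clamp"`` (amplitude in mV, exclusive per neuron per step).  An
    optional per-step probability makes the stimulus fire stochastically;
    draws come from a dedicated per-stimulus stream so they do not depend
    on device placement.
    """

    target: int  # network neuron ID; resolved to a device index at build
    kind: str
    amplitude: float
    start_step: int
    end_step: int
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("current", "clamp"):
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if self.start_step >= self.end_step:
            raise ConfigurationError(
                "stimulus window must satisfy start < end "
                f"(got [{self.start_step}, {self.end_step}))"
            )
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("stimulus probability must be in [0, 1]")

    def active(self, t: int) -> bool:
        return self.start_step <= t < self.end_step


class StimulusInstance:
    """A stimulus bound to a device-local neuron index, with its own RNG."""

    def __init__(self, spec: StimulusSpec, local_index: int, seed: int, sid: int):
        self.spec = spec
        self.local_index = local_index
        self.sid = sid
        self._rng = child_rng(seed, f"stimulus/{sid}") if spec.probability is not None else None
        self._rng_step = 0

    def draw(self, t: int) -> bool:
        """Stochastic gate for step ``t``; one uniform is drawn per step the
        stimulus window covers, so results are placement-independent."""
        if self._rng is None:
            return True
        while self._rng_step < t:
            self._rng.random()
            self._rng_step += 1
        if self._rng_step == t:
            u = self._rng.random()
            self._rng_step = t + 1
            return u < self.spec.probability
        raise RuntimeError("stimulus RNG consumed out of order")


def input_update(
    stimuli: Sequence[StimulusInstance],
    t: int,
    n_local_neurons: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One input-stage step for a device.

    Returns ``(input_current, clamp_voltage, clamp_select)``; currents from
    co-targeted stimuli add in stimulus-list order, clamp bits are set for
    exactly the clamped neurons.  Two clamps on one neuron in one step are
    rejected when the network is built, not here.
    """
    current = np.zeros(n_local_neurons, dtype=np.float64)
    clamp_v = np.zeros(n_local_neurons, dtype=np.float64)
    clamp_sel = np.zeros(n_local_neurons, dtype=bool)
    for inst in stimuli:
        if not inst.spec.active(t) or not inst.draw(t):
            continue
        if inst.spec.kind == "current":
            current[inst.local_index] += inst.spec.amplitude
        else:
            clamp_v[inst.local_index] = inst.spec.amplitude
            clamp_sel[inst.local_index] = True
    return current, clamp_v, clamp_sel
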