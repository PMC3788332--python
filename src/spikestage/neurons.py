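"""Built-in neuron model families and firing-pattern classification.

Two plugin families ship with the simulator:

* **IZH** — the two-variable quadratic model

  .. math::

     v' = 0.04 v^2 + 5 v + 140 - u + I, \\qquad u' = a (b v - u)

  with the reset :math:`v \\leftarrow c,\\; u \\leftarrow u + d` when the
  voltage reaches the 30 mV peak.  Integration uses the scheme published
  with the model: per 1 ms engine step, two 0.5 ms Euler half-steps for
  ``v`` followed by one full Euler step for ``u``.  On a firing step the
  reported voltage is the 30 mV peak (the post-reset value ``c`` becomes
  visible the following step), so voltage traces show the spike.

* **Hybrid LIF** — a leaky integrator whose subthreshold dynamics may be
  shaped by conductance channels in the Hodgkin–Huxley formalism (gating
  variables relaxing to voltage- or calcium-dependent steady states), and
  whose action potential is not integrated at all: when the voltage
  crosses threshold from below, a user-specified per-step voltage template
  is played back verbatim, after which integration resumes from the
  template's last sample.  A refractory countdown (at least as long as the
  template) suppresses further threshold tests.

Cells may consist of several compartments; each compartment is simulated
as a neuron-like element and linear conductive couplings to sibling
compartments are accumulated into the same current buffer the channels
write.  Compartments of one cell are always colocated on one device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NumericError",
    "IzhParams",
    "IzhPopulation",
    "CANONICAL_IZH",
    "VoltageGatedChannelParams",
    "CalciumActivatedChannelParams",
    "LIFCompartmentParams",
    "LIFCompartmentState",
    "LIFPopulation",
    "CANONICAL_LIF",
    "CANONICAL_DRIVE",
    "channel_currents",
    "classify_pattern",
]

IZH_PEAK_MV = 30.0


class NumericError(RuntimeError):
    """State became non-finite; carries the element and step for diagnosis."""


# --------------------------------------------------------------------------
# Izhikevich family
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IzhParams:
    """Parameters of the quadratic two-variable model.

    ``a`` (1/ms) sets the recovery time scale, ``b`` couples recovery to
    voltage, ``c`` (mV) is the after-spike reset, ``d`` the recovery
    increment, ``peak`` (mV) the spike cutoff.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    peak: float = IZH_PEAK_MV

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("IZH parameter a must be > 0")
        if self.peak <= self.c:
            raise ValueError("IZH peak must exceed the reset value c")


#: Canonical parameter sets from the model's published parameterisation:
#: regular-spiking, fast-spiking, and bursting (chattering) cortical cells.
CANONICAL_IZH: dict[str, IzhParams] = {
    "RS": IzhParams(a=0.02, b=0.2, c=-65.0, d=8.0),
    "FS": IzhParams(a=0.10, b=0.2, c=-65.0, d=2.0),
    "B": IzhParams(a=0.02, b=0.2, c=-50.0, d=2.0),
}


class IzhPopulation:
    """Vectorised IZH state for one plugin's neurons on one device.

    All neurons in the population share the engine step ``dt`` but may have
    distinct parameters.  ``v`` starts at the reset value ``c`` and ``u`` at
    ``b * c`` (the resting coupling), the conventional initial condition.
    """

    model = "izh"

    def __init__(self, params: Sequence[IzhParams], dt: float = 1.0) -> None:
        self.dt = float(dt)
        self.a = np.array([p.a for p in params], dtype=np.float64)
        self.b = np.array([p.b for p in params], dtype=np.float64)
        self.c = np.array([p.c for p in params], dtype=np.float64)
        self.d = np.array([p.d for p in params], dtype=np.float64)
        self.peak = np.array([p.peak for p in params], dtype=np.float64)
        self.v = self.c.copy()
        self.u = self.b * self.c

    def __len__(self) -> int:
        return self.v.size

    def step(self, current: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Advance one engine step under total input ``current``.

        Returns ``(reported_voltage, fired)``.  The reported voltage on a
        firing step is the peak; the state voltage is reset to ``c``.
        """
        v, u = self.v, self.u
        half = 0.5 * self.dt
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(2):
                v = v + half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
                # peak clamp: the quadratic diverges past threshold, so stop
                # the half-step at the cutoff; keeps firing-step dynamics
                # regular (non-finite states still propagate and are caught)
                v = np.minimum(v, self.peak)
            u = u + self.dt * self.a * (self.b * v - u)
        fired = v >= self.peak
        reported = np.where(fired, self.peak, v)
        self.v = np.where(fired, self.c, v)
        self.u = np.where(fired, u + self.d, u)
        if not (np.isfinite(self.v).all() and np.isfinite(self.u).all()):
            bad = int(np.nonzero(~np.isfinite(self.v) | ~np.isfinite(self.u))[0][0])
            raise NumericError(f"IZH state diverged at plugin-local neuron {bad}")
        return reported, fired


# --------------------------------------------------------------------------
# Hybrid LIF family
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VoltageGatedChannelParams:
    """Voltage-gated potassium channel (Boltzmann gate, first-order kinetics).

    Steady state ``m_inf(v) = 1 / (1 + exp(-(v - v_half)/slope))``; the gate
    relaxes toward it with time constant ``tau_ms``, and the channel adds
    ``g_max * m**p * (e_rev - v)`` to the compartment's current buffer.
    """

    g_max: float = 0.0
    e_rev: float = -80.0
    v_half: float = -40.0
    slope: float = 5.0
    tau_ms: float = 10.0
    p: int = 1

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.tau_ms <= 0:
            raise ValueError("Kv channel needs g_max >= 0 and tau_ms > 0")


@dataclass(frozen=True)
class CalciumActivatedChannelParams:
    """Calcium-activated potassium channel (after-hyperpolarisation current).

    The gate saturates with internal calcium via a Hill function
    ``Ca**e / (Ca**e + half**e)`` and is treated as instantaneous; calcium
    itself jumps by ``ca_increment`` on each spike and otherwise decays
    exponentially with ``ca_tau_ms``.  Current added:
    ``g_max * gate * (e_rev - v)``.
    """

    g_max: float = 0.0
    e_rev: float = -80.0
    ca_half: float = 5.0
    exponent: float = 1.0
    ca_increment: float = 1.0
    ca_tau_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.ca_tau_ms <= 0:
            raise ValueError("KCa channel needs g_max >= 0 and ca_tau_ms > 0")


@dataclass(frozen=True)
class LIFCompartmentParams:
    """One compartment of a hybrid LIF cell.

    ``c_m`` is membrane capacitance (nF), ``tau_m`` the leak time constant
    (ms), so a current I (nA) moves the voltage at I/c_m mV/ms.  The spike
    template is an explicit per-step voltage sequence (mV) played back from
    the threshold-crossing step; the refractory period must cover it.
    """

    c_m: float = 1.0
    tau_m: float = 10.0
    e_rest: float = -65.0
    v_threshold: float = -50.0
    spike_template: tuple[float, ...] = (30.0, 0.0, -40.0, -65.0)
    refractory_steps: int = 4
    kv_channels: tuple[VoltageGatedChannelParams, ...] = ()
    kca_channels: tuple[CalciumActivatedChannelParams, ...] = ()

    def __post_init__(self) -> None:
        if not self.spike_template:
            raise ValueError("spike template must be non-empty")
        if self.refractory_steps < len(self.spike_template):
            raise ValueError(
                "refractory period must be at least the template length"
            )
        if self.c_m <= 0 or self.tau_m <= 0:
            raise ValueError("c_m and tau_m must be positive")


@dataclass
class LIFCompartmentState:
    """Mutable per-compartment state.

    ``template_pos`` is -1 while inactive; while active the voltage equals
    the template sample at that position.  Gating values stay in [0, 1].
    """

    v: float
    template_pos: int = -1
    refractory_remaining: int = 0
    ca: float = 0.0
    kv_gates: list[float] = field(default_factory=list)
    fired: bool = False


def channel_currents(
    state: LIFCompartmentState,
    params: LIFCompartmentParams,
    dt: float,
) -> float:
    """Advance channel gates one step and return their summed current.

    Gates are updated with the pre-integration voltage (channel plugins run
    before the compartment updater each step, reading the state it published
    the previous step), then each channel contributes
    ``g_max * gate**p * (e_rev - v)``.  Contributions are summed in channel
    list order so the total is schedule-independent.
    """
    v = state.v
    total = 0.0
    for i, ch in enumerate(params.kv_channels):
        m_inf = 1.0 / (1.0 + math.exp(-(v - ch.v_half) / ch.slope))
        m = state.kv_gates[i]
        m += dt * (m_inf - m) / ch.tau_ms
        m = min(1.0, max(0.0, m))
        state.kv_gates[i] = m
        total += ch.g_max * m**ch.p * (ch.e_rev - v)
    for ch in params.kca_channels:
        ca_e = state.ca**ch.exponent
        gate = ca_e / (ca_e + ch.ca_half**ch.exponent) if ca_e > 0 else 0.0
        total += ch.g_max * gate * (ch.e_rev - v)
    return total


def lif_compartment_step(
    state: LIFCompartmentState,
    params: LIFCompartmentParams,
    i_channels: float,
    i_syn: float,
    i_input: float,
    clamp: Optional[float],
    dt: float,
) -> LIFCompartmentState:
    """Advance one compartment one engine step (in place; also returned).

    Precedence: a voltage clamp wins over everything (no threshold test, any
    template playback is aborted); an active template plays back verbatim,
    ignoring input; otherwise the leaky integrator runs and a
    below-to-above threshold crossing starts playback, marking ``fired``
    only on the crossing step.
    """
    state.fired = False
    if clamp is not None:
        state.v = clamp
        state.template_pos = -1
        if state.refractory_remaining > 0:
            state.refractory_remaining -= 1
        _update_ca(state, params, dt)
        return state

    if state.template_pos >= 0:
        nxt = state.template_pos + 1
        if nxt < len(params.spike_template):
            state.template_pos = nxt
            state.v = params.spike_template[nxt]
            if state.refractory_remaining > 0:
                state.refractory_remaining -= 1
            _update_ca(state, params, dt)
            return state
        state.template_pos = -1  # playback over: integrate this step

    if state.refractory_remaining > 0:
        # absolute refractory beyond the template: membrane unresponsive,
        # held at the template's last sample until the countdown expires
        state.refractory_remaining -= 1
        _update_ca(state, params, dt)
        return state

    v_old = state.v
    i_total = i_channels + i_syn + i_input
    v_new = v_old + dt * (
        -(v_old - params.e_rest) / params.tau_m + i_total / params.c_m
    )
    if not math.isfinite(v_new):
        raise NumericError("LIF compartment voltage diverged")
    if v_old < params.v_threshold and v_new >= params.v_threshold:
        state.fired = True
        state.template_pos = 0
        state.v = params.spike_template[0]
        state.refractory_remaining = params.refractory_steps - 1
    else:
        state.v = v_new
    _update_ca(state, params, dt)
    return state


def _update_ca(
    state: LIFCompartmentState, params: LIFCompartmentParams, dt: float
) -> None:
    """Spike-triggered calcium: jump on fired steps, exponential decay else."""
    if not params.kca_channels:
        return
    ch = params.kca_channels[0]
    if state.fired:
        state.ca += ch.ca_increment
    else:
        state.ca *= math.exp(-dt / ch.ca_tau_ms)


class LIFPopulation:
    """Hybrid-LIF plugin state for one device: a list of compartments.

    ``couplings[i]`` lists ``(other_local_index, conductance)`` pairs whose
    current ``g * (v_other - v_i)`` is added to compartment ``i``'s channel
    buffer, using the sibling voltages from the previous step (all siblings
    are guaranteed colocated, so those voltages are device-local).
    """

    model = "lif"

    def __init__(
        self,
        params: Sequence[LIFCompartmentParams],
        couplings: Optional[Sequence[Sequence[tuple[int, float]]]] = None,
        dt: float = 1.0,
    ) -> None:
        self.dt = float(dt)
        self.params = list(params)
        self.couplings = (
            [list(c) for c in couplings]
            if couplings is not None
            else [[] for _ in params]
        )
        self.states = [
            LIFCompartmentState(
                v=p.e_rest, kv_gates=[0.0] * len(p.kv_channels)
            )
            for p in self.params
        ]

    def __len__(self) -> int:
        return len(self.states)

    def step(
        self,
        i_syn: np.ndarray,
        i_input: np.ndarray,
        clamp_values: np.ndarray,
        clamp_select: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance all compartments; returns (voltages, fired)."""
        v_prev = [s.v for s in self.states]
        voltages = np.empty(len(self.states), dtype=np.float64)
        fired = np.zeros(len(self.states), dtype=bool)
        for i, (st, p) in enumerate(zip(self.states, self.params)):
            i_ch = channel_currents(st, p, self.dt)
            for other, g in self.couplings[i]:
                i_ch += g * (v_prev[other] - v_prev[i])
            clamp = float(clamp_values[i]) if clamp_select[i] else None
            try:
                lif_compartment_step(
                    st, p, i_ch, float(i_syn[i]), float(i_input[i]), clamp, self.dt
                )
            except NumericError as exc:
                raise NumericError(
                    f"LIF compartment {i} (plugin-local): {exc}"
                ) from exc
            voltages[i] = st.v
            fired[i] = st.fired
        return voltages, fired


#: Canonical hybrid-LIF parameter sets for the three validation patterns.
#: Regular spiking adapts through a slow, far-from-saturation
#: after-hyperpolarisation (Ca-activated K) current, so inter-spike
#: intervals lengthen monotonically under constant drive.  Fast spiking
#: uses a fast membrane, a two-step template and no adaptation.  Bursting
#: is a square-wave burster: a regenerative depolarising channel
#: (persistent-sodium-like parameterisation of the voltage-gated channel,
#: reversal +30 mV, activating above -55 mV) sustains spiking while the
#: Ca-activated K current accumulates, silences the cell, and releases it
#: again once calcium has decayed.
CANONICAL_LIF: dict[str, LIFCompartmentParams] = {
    "RS": LIFCompartmentParams(
        c_m=1.0,
        tau_m=10.0,
        e_rest=-65.0,
        v_threshold=-50.0,
        spike_template=(30.0, 0.0, -40.0, -65.0),
        refractory_steps=4,
        kca_channels=(
            CalciumActivatedChannelParams(
                g_max=0.1,
                e_rev=-80.0,
                ca_half=12.0,
                exponent=1.0,
                ca_increment=1.0,
                ca_tau_ms=300.0,
            ),
        ),
    ),
    "FS": LIFCompartmentParams(
        c_m=1.0,
        tau_m=5.0,
        e_rest=-65.0,
        v_threshold=-50.0,
        spike_template=(30.0, -65.0),
        refractory_steps=2,
    ),
    "B": LIFCompartmentParams(
        c_m=1.0,
        tau_m=10.0,
        e_rest=-65.0,
        v_threshold=-50.0,
        spike_template=(30.0, -60.0),
        refractory_steps=2,
        kv_channels=(
            VoltageGatedChannelParams(
                g_max=0.4,
                e_rev=30.0,
                v_half=-55.0,
                slope=3.0,
                tau_ms=5.0,
                p=1,
            ),
        ),
        kca_channels=(
            CalciumActivatedChannelParams(
                g_max=2.0,
                e_rev=-80.0,
                ca_half=4.0,
                exponent=2.0,
                ca_increment=1.0,
                ca_tau_ms=50.0,
            ),
        ),
    ),
}

#: Suprathreshold drive currents used by the firing-pattern validation
#: suite, per family and pattern.
CANONICAL_DRIVE: dict[str, dict[str, float]] = {
    "izh": {"RS": 10.0, "FS": 10.0, "B": 10.0},
    "lif": {"RS": 3.0, "FS": 4.0, "B": 1.0},
}


# --------------------------------------------------------------------------
# Firing-pattern classification
# --------------------------------------------------------------------------


def classify_pattern(
    spike_steps: Sequence[int],
    dt: float = 1.0,
    window_ms: float | None = None,
) -> str:
    """Label a single-neuron spike train as RS, FS, B or other.

    * ``B`` (bursting): bimodal inter-spike-interval distribution whose
      intra-burst mean is below a quarter of the inter-burst mean.
    * ``FS`` (fast spiking): mean rate at or above 50 Hz with ISI
      coefficient of variation below 0.2 (high and regular).
    * ``RS`` (regular spiking): monotone non-decreasing ISIs with a
      last/first ratio above 1.2 (spike-frequency adaptation).

    ``window_ms`` restricts the analysis to spikes before that time.
    Fewer than two spikes (no ISI) yields ``"other"``.
    """
    times = np.asarray(spike_steps, dtype=np.float64) * dt
    if window_ms is not None:
        times = times[times < window_ms]
    if times.size < 2:
        return "other"
    isis = np.diff(times)

    # bursting: split the sorted ISIs at the largest multiplicative gap
    if isis.size >= 3:
        s = np.sort(isis)
        gaps = s[1:] / np.maximum(s[:-1], 1e-12)
        k = int(np.argmax(gaps)) + 1
        intra, inter = s[:k], s[k:]
        if (
            intra.size >= 2
            and inter.size >= 1
            and intra.mean() < 0.25 * inter.mean()
        ):
            return "B"

    mean_isi = float(isis.mean())
    rate_hz = 1000.0 / mean_isi
    cv = float(isis.std() / mean_isi) if mean_isi > 0 else math.inf
    if rate_hz >= 50.0 and cv < 0.2:
        return "FS"

    if np.all(np.diff(isis) >= 0) and isis[-1] / isis[0] > 1.2:
        return "RS"
    return "other"
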