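# Methods

## Scope and intent

spikestage reproduces the *logical* architecture of a cluster-scale
spiking network simulator inside one process: the same element kinds
(neurons, synapses, stimuli, reports), the same four-level ID scope
hierarchy (plugin / device / machine / global), the same staged
dataflow with bounded buffer pools, and the same communication design
(one bit of spiking state per element, exchanged globally each step).
Real MPI transport, CUDA kernels and wall-clock performance are out of
scope; the machine scope exists in the API but hosts all devices.

## ID scopes and bit vectors

Every element kind gets zero-based IDs per scope. Between plugins, ID
ranges are padded to 32-bit word boundaries, so no two plugins'
elements share a machine word: plugins can write their slice of any
shared word array or bit vector without synchronisation. The packed
spike vector stores bit *i* of element *e* in word `e div 32`, bit
`e mod 32` (LSB-first; the convention is arbitrary but fixed for test
determinism). Padding is applied per element kind independently. A
consequence checked by the acceptance suite: at word-aligned counts the
exchanged payload is exactly 1 bit per neuron — 10⁶ bits (1 Mb) per
update for a million cells.

## Load balancing

Device power = clock rate × cores (a deliberately crude rating: memory
bandwidth is ignored). Neuron cost = afferent synapse count, since
synapses dominate compute and are stored with their postsynaptic
neuron. Assignment is greedy over neurons in decreasing cost; each goes
to the device with the smallest assigned-cost/power ratio at that
moment. Ties — equal ratios, equal costs — are broken by device list
order and ascending neuron ID, making placement fully deterministic
(the underlying rule leaves them unspecified). Synapses and stimuli are
then colocated with their target neuron's device, and all compartments
of one cell are pulled onto one device so cross-compartment couplings
stay local. Presynaptic neurons may be remote; postsynaptic never are.

## Neuron models

### IZH

`v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, reset `v←c, u←u+d`
at the 30 mV peak. Integration: per 1 ms engine step, two 0.5 ms Euler
half-steps for `v` then one full Euler step for `u` — the scheme
published with the model. Each half-step clamps `v` at the peak: the
quadratic diverges explosively past threshold, and without the clamp
the overshoot magnitude (and hence the recovery increment through
`u' ∝ bv`) depends chaotically on where in the step the crossing falls,
which injects multi-millisecond inter-spike-interval jitter. With the
clamp the firing-step dynamics are regular and the canonical parameter
sets express clean RS/FS/bursting patterns. The voltage *reported* on a
firing step is the 30 mV peak, not the post-reset `c`, so traces and
rasters agree visually. Non-finite states halt the run with the step
and element in the error.

### Hybrid LIF

Subthreshold: `dv/dt = −(v − E_rest)/τ_m + I_total/C_m`, forward Euler
at dt = 1 ms. `I_total` sums channel currents, synaptic current,
stimulus current, and (for multi-compartment cells) linear conductive
couplings `g·(v_sibling − v)` computed from the previous step's
colocated sibling voltages. Threshold crossing *from below* triggers
the spike template: the voltage follows the user-given per-step mV
sequence verbatim, `fired` is set only on the crossing step, and input
is ignored during playback (accumulating it was considered and
rejected: replaying a fixed spike shape is the model's premise).
After the template, any remaining refractory steps hold the membrane
at the template's last sample, unresponsive. This "absolute refractory
hold" is a deliberate choice: if the membrane integrated during
refractory, a suppressed crossing could leave `v` parked above
threshold with no subsequent below-to-above crossing, silencing the
cell forever. A voltage clamp wins over everything — it sets `v`,
aborts any playback, and clamped steps never fire.

Channels follow the HH formalism with forms fixed here (the originating
design left exact kinetics to external documentation, so all constants
are user parameters):

* voltage-gated: `m_inf(v) = 1/(1+exp(−(v−v_half)/slope))`, first-order
  relaxation with time constant τ, current `g·m^p·(E_rev − v)`. A
  negative slope or a depolarised reversal are legitimate
  parameterisations (an inward, regenerative current).
* calcium-activated: instantaneous Hill gate `Ca^e/(Ca^e + half^e)`;
  calcium jumps by a fixed increment on fired steps and otherwise
  decays exponentially. Under periodic firing with period T the
  post-spike calcium converges to `inc/(1 − f^(T−1))`, `f = exp(−dt/τ)`
  — the analytic oracle used in tests.

Channel updates run before integration each step, reading the state the
compartment published the previous step (matching the
channel-plugins-then-compartment-updater pipeline); the threshold test
therefore uses the post-channel-update voltage.

### Canonical pattern sets

IZH uses the standard published RS/FS/chattering values. The LIF sets
were designed once against the classifier below and then frozen:

* **RS**: moderate, slow (τ_Ca = 300 ms, far from saturation)
  after-hyperpolarisation current ⇒ monotonically lengthening ISIs.
* **FS**: fast membrane (τ_m = 5 ms), two-step template, no adaptation
  ⇒ ~125 Hz regular firing.
* **B**: a square-wave burster — a persistent-sodium-like regenerative
  channel (reversal +30 mV, activating above −55 mV, τ = 5 ms)
  sustains spiking while calcium accumulates; the strong KCa current
  (g = 2, Hill exponent 2) silences the cell; firing resumes when
  calcium decays (τ_Ca = 50 ms). Pure spike-triggered adaptation with
  an instantaneous gate cannot burst repetitively here: the
  single-spike limit cycle is always stable (longer intervals decay
  more calcium, shortening the next interval — negative feedback), so a
  second, regenerative mechanism is required.

Drive currents: IZH 10 (all), LIF 3/4/1 nA (RS/FS/B).

### Pattern classification

Given a spike train (≥ 2 spikes; optional analysis window), in order:
**bursting** if the sorted ISIs split at their largest multiplicative
gap into a non-trivial short group (≥ 2) whose mean is < 0.25× the long
group's mean; else **fast-spiking** if the mean rate is ≥ 50 Hz with
ISI coefficient of variation < 0.2; else **regular-spiking** if ISIs
are monotone non-decreasing with last/first > 1.2; else *other*.

## Synapses and stimuli

A presynaptic spike at step t with delay d ≥ 1 first contributes
current at step t+d (template index 0). The minimum delay of 1 step is
what makes a same-step loop impossible and lets devices run ahead. The
default waveform is a discretised double exponential (1 ms rise, 3 ms
decay, peak-normalised, truncated at 1 % of peak, ~15 samples); weights
carry the magnitude and sign. Events are per-synapse-plugin,
double-buffered (previous/next list per step). Plasticity, conductance
synapses and gap junctions are excluded. Stimuli inject additive
current or clamp voltage over half-open step windows; overlapping
clamps on one neuron are rejected at parse time. Stochastic stimuli
draw one uniform per covered step from a per-stimulus stream, so their
realisation is independent of device placement.

## Engine semantics

Stages per device: input → (neuron ← synapse ← firing table ← exchange
← neuron …), connected by publishers with capacity B = 2 by default
(double buffering; B = 1 also works, fully lock-step). A publisher with
all buffers outstanding cannot run — no stage gets unboundedly ahead
(the input stage, with no dependencies, would otherwise simulate the
whole run before the first neuron update). The firing table is
logically a ring of `max local delay + 1` synapse-bit rows; after
processing the global vector for step t it publishes the completed row
t + N_min, and rows 0 .. N_min−1 — unreachable because delays are ≥ 1 —
are pre-published as zeros to prime the pipeline. Publication is eager
within the N_min window.

The scheduler is a serial deterministic loop over stages
(run-until-blocked); concurrency is treated as an optimisation the
audited publish/acquire/release contract would equally permit, not a
semantic. An optional audit log records every buffer operation; tests
replay it to check the capacity bound, the stamp contract (a stage
only ever consumes buffers of its own step), and the lookahead bound.

**Partition invariance** is a design guarantee, not an accident:
per-neuron current sums accumulate in a fixed order — ascending event
arrival step, then ascending source network ID (sequential `bincount`)
— and stimuli add in ascending stimulus index. Atomic/unordered
accumulation was rejected precisely because it makes floating-point
totals schedule-dependent. Neurons, synapses and stimuli are identified
in reports by their *network IDs* (document order), which are stable
across partitionings; scoped IDs are internal.

## Reports

One reporter per machine; it subscribes to the needed publishers by
string identifier (`neuron_out[d]`, `input_current[d]`,
`syn_current[d]`), extracts device-local slices, and reduces aggregates
(spike counts) across devices before writing. Sinks are plain CSV with
`#` metadata lines (network content hash, seed, dt): rasters as
`step,neuron`, traces as one row per cadence tick with columns in
ascending element ID, counts as `step,count`. Floats are written with
shortest round-trip `repr`, so identical runs produce identical bytes.

## Network documents and the generator

Documents are JSON (a clean format defined here; no compatibility with
any legacy text grammar). All defaults are materialised at parse;
probabilistic connections expand through named child streams of the
document seed (`connections/<i>`, `stimulus/<i>`, `generator`), so
subsystems cannot reshuffle each other's draws and
parse → serialize → parse is a fixed point.

The benchmark generator emits n neurons with exactly
`round(n × ratio)` synapses (default ratio 100), pre/post drawn
uniformly with replacement — self-loops and duplicate pairs allowed;
rejection-free at any ratio — and integer delays uniform in [1, 20].
Defaults beyond the ratio and delay range are this package's choices,
fixed once: an 80/20 excitatory/inhibitory split in the style of the
classic random cortical network (excitatory weights U(0, 0.5) nA from
RS cells, inhibitory U(−1, 0) nA from FS cells) and a noisy per-neuron
stimulus (15 nA with probability 0.05 per step), which together
produce ~7 Hz mean population rates. The generator emulates benchmark
*scale and connectivity statistics*, not any particular circuit:
passing tests on it demonstrates architectural correctness
(conservation, invariance, determinism), not biological fidelity of any
specific model.

## Problem sizes and numerical choices

The test and acceptance runs use: 500 neurons / 50,000 synapses /
1,000 steps for the partition-invariance and determinism checks (1, 2
and 4 devices), 1,000 steps with delays 1–20 for firing-table
conservation, 10 s of 1 ms steps for the IZH oracle comparison, and
1 s for the pattern suite — sizes chosen so the whole suite completes
in seconds while exercising every padded-layout and multi-device code
path. All state is float64. The IZH oracle comparison demands *exact*
spike-time equality (same arithmetic, same order); cross-synapse
current totals are compared to the naive convolution oracle at 1e-12
relative, since only the summation order differs. dt is fixed at 1 ms
in all validated configurations; other values run but are untested
against the oracles.

## Known limitations

No synaptic plasticity; current-based (not conductance-based)
synapses; no Hodgkin–Huxley Na/K neuron type; the plugin registry is
in-process only (no loading of user shared objects); single process —
the exchange stage emulates the cluster broadcast deterministically;
and the device power metric ignores memory bandwidth, which the
balancing rule inherits by design.
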