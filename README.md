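# spikestage

A desk-scale, staged spiking neural network simulator for computational
neuroscientists who want the *architecture* of a distributed CPU/GPU
cluster simulator — scoped element IDs, packed bit-vector spike exchange,
cost/power load balancing, a delay-indexed synaptic firing table, and
bounded publisher–subscriber stage pipelines — in a single deterministic
Python process that can be inspected, audited and tested.

## The model

Two neuron plugin families are built in.

**Izhikevich (IZH)** — the two-variable quadratic model

```
v' = 0.04 v² + 5v + 140 − u + I        u' = a(bv − u)
if v ≥ 30 mV:  v ← c,  u ← u + d
```

integrated at the engine step of dt = 1 ms as two 0.5 ms Euler
half-steps for `v` (clamped at the 30 mV peak) and one full step for
`u`. Canonical parameter sets give regular-spiking
(a=0.02, b=0.2, c=−65, d=8), fast-spiking (a=0.1, d=2) and bursting
(c=−50, d=2) cells.

**Hybrid LIF** — subthreshold dynamics are a leaky integrator shaped by
Hodgkin–Huxley-formalism channels,

```
C_m dv/dt = −(v − E_rest) C_m/τ_m + I_channels + I_syn + I_input
```

with a voltage-gated channel (Boltzmann gate, first-order kinetics) and
a calcium-activated potassium channel (Hill-saturating gate over a
spike-incremented, exponentially decaying calcium pool). When `v`
crosses threshold from below, the membrane does not integrate an action
potential: a user-specified spike-shape template (a per-step mV
sequence) is played back verbatim, followed by an absolute refractory
period.

**Synapses** deliver a weighted current *waveform* (a peak-normalised
template, by default a 1 ms-rise / 3 ms-decay double exponential) that
starts an integer delay ≥ 1 step after the presynaptic spike;
overlapping waveforms sum linearly as independent playback events.

**Distribution.** Each logical device is rated `power = clock × cores`;
each neuron costs its afferent synapse count; neurons are assigned
greedily in decreasing cost to the device with the lowest load/power
ratio, and every synapse and stimulus is colocated with its
postsynaptic neuron's device. Spiking state is the only cross-device
traffic: one bit per neuron, word-padded between plugins, so a
million-cell update is exactly one megabit.

**The engine** runs five stages per device (input, synapse, neuron,
exchange, firing table) plus reporters, connected by bounded
publish/acquire/release buffer pools; the firing table lets devices run
ahead of each other by up to the minimum synaptic delay. The scheduler
is serial and deterministic; per-neuron current sums use a fixed
accumulation order, so **rasters and voltage traces are bit-identical
for any device partitioning of the same network and seed**.

## Worked example

`python examples/benchmark_network.py` generates a 300-neuron random
network at the standard 100:1 synapse:neuron ratio (80/20
excitatory/inhibitory, noisy current drive), runs it on two unequal
devices and on one, and prints:

```
network: 300 neurons, 30000 synapses
device shares (fast/slow, power 3088/1000): 226/74
activity: 1053 spikes in 500 ms -> 7.0 Hz mean rate
partition invariant: True
```

The faster device (power 3088 vs 1000) receives ~3× the neurons; the
network fires at a cortical-like ~7 Hz; and both partitionings produce
byte-identical report files. `python examples/firing_patterns.py` runs
the model-validation suite (each family driven at its canonical
current):

```
izh RS:  22 spikes/s, classified RS
izh FS:  89 spikes/s, classified FS
izh B :  69 spikes/s, classified B
lif RS:  44 spikes/s, classified RS
lif FS: 125 spikes/s, classified FS
lif B :  37 spikes/s, classified B
```

and `python examples/spike_vector_payload.py` prints the
one-bit-per-cell communication argument.

## Command line

```
spikestage validate net.json          # parse + validate, exit 0/2
spikestage run net.json --device gpu0:1544:2 --device cpu0:1000:1 \
    --duration 1000 --seed 5 --out results/
spikestage generate --neurons 1000 --ratio 100 --seed 42 --out bench.json
spikestage patterns --out patterns/   # RS/FS/B validation traces
spikestage describe-models            # canonical parameters
```

Network documents are JSON (groups, connections, stimuli, reports); see
`docs/methods.md` for the format and every default.

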