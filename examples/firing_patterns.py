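"""Validate the built-in neuron models against the three classic firing
patterns: drive one cell of each family with its canonical current and
classify the resulting spike train.

Each line prints the family, the intended pattern, the number of spikes
in one simulated second, and the label the inter-spike-interval
classifier assigns; a matching label means the model expresses the
intended electrophysiological class.
"""

from spikestage.patterns import run_suite

for r in run_suite(duration_ms=1000):
    rate = len(r.spike_steps)  # spikes per simulated second
    print(
        f"{r.family:3s} {r.pattern:2s}: {rate:3d} spikes/s, "
        f"classified {r.classification}"
    )
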