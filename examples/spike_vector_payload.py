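"""The communication argument for bit-vector spike exchange: with one bit
per cell, a million-neuron update fits in one megabit — small enough for
commodity gigabit Ethernet at a 1 ms time-step.

Printed: the padded payload size of the global spike vector for 10^6
neurons and the per-neuron cost in bits.
"""

from spikestage import allocate_layout

layout = allocate_layout([("cells", 1_000_000)])
bits = layout.total_bits
print(f"global spike vector for 1,000,000 neurons: {bits:,} bits "
      f"({bits / 8 / 1024:.0f} KiB) per update")
print(f"per neuron: {bits / layout.populated_count:.0f} bit")

# word padding between plugins: a one-element plugin still occupies a word
two = allocate_layout([("first", 1), ("second", 8)])
print(f"plugin padding: second plugin starts at bit {two.partitions[1].base}")
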