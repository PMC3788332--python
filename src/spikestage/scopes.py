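"""Scoped identifier layouts and the packed spike bit vector.

Simulation elements (neurons, synapses, stimuli) are referenced in four
nested scopes mirroring a cluster hierarchy: plugin, device, machine and
global.  Within each scope every element gets a zero-based ID, and the ID
ranges of different plugins are padded to 32-bit word boundaries so that
no two plugins' elements ever share a machine word.  That property is what
lets per-plugin updates write their slice of a shared bit vector without
synchronisation.

IDs are unique only within one element kind: a neuron and a synapse may
both have global ID 0.

The spike state of a population is a :class:`SpikeBitVector`: one bit per
element, packed LSB-first into ``uint32`` words (bit ``i`` lives in word
``i // 32`` at bit position ``i % 32``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

WORD_BITS = 32

__all__ = [
    "WORD_BITS",
    "Scope",
    "ConfigurationError",
    "IDLayout",
    "SpikeBitVector",
    "allocate_layout",
    "padded_length",
    "translate",
]


class Scope(str, Enum):
    """Nesting levels of the ID hierarchy, innermost first."""

    PLUGIN = "plugin"
    DEVICE = "device"
    MACHINE = "machine"
    GLOBAL = "global"


class ConfigurationError(ValueError):
    """Invalid network/device/layout configuration supplied by the user."""


def padded_length(count: int) -> int:
    """Number of bits occupied by ``count`` elements after padding to a word."""
    if count < 0:
        raise ConfigurationError(f"negative element count: {count}")
    return math.ceil(count / WORD_BITS) * WORD_BITS


@dataclass(frozen=True)
class Partition:
    """One plugin's slice of a scope: ``count`` elements starting at ``base``."""

    plugin: str
    count: int
    base: int

    def contains(self, scoped_id: int) -> bool:
        return self.base <= scoped_id < self.base + self.count


@dataclass
class IDLayout:
    """Word-padded ID assignment for one element kind within one scope.

    ``partitions`` are laid out in order; each partition's base offset is the
    previous base plus the previous count rounded up to a multiple of 32, so
    every partition starts on a word boundary and padding-hole IDs (between a
    partition's populated range and the next base) are never valid.
    """

    partitions: list[Partition]

    @property
    def total_bits(self) -> int:
        """Padded bit length of the whole layout (a multiple of 32)."""
        if not self.partitions:
            return 0
        last = self.partitions[-1]
        return last.base + padded_length(last.count)

    @property
    def total_words(self) -> int:
        return self.total_bits // WORD_BITS

    @property
    def populated_count(self) -> int:
        return sum(p.count for p in self.partitions)

    def base_of(self, plugin: str) -> int:
        for p in self.partitions:
            if p.plugin == plugin:
                return p.base
        raise KeyError(plugin)

    def partition_of(self, scoped_id: int) -> Partition:
        """Partition owning a populated scoped ID (padding holes are invalid)."""
        for p in self.partitions:
            if p.contains(scoped_id):
                return p
        raise ConfigurationError(
            f"ID {scoped_id} falls in a padding hole or outside the layout"
        )

    def is_populated(self, scoped_id: int) -> bool:
        return any(p.contains(scoped_id) for p in self.partitions)

    def populated_ids(self) -> Iterable[int]:
        for p in self.partitions:
            yield from range(p.base, p.base + p.count)

    # -- plain-JSON dump/restore, used by debug tooling and test fixtures --

    def to_json(self) -> str:
        doc = {
            "word_bits": WORD_BITS,
            "partitions": [
                {"plugin": p.plugin, "count": p.count, "base": p.base}
                for p in self.partitions
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IDLayout":
        doc = json.loads(text)
        layout = cls(
            partitions=[
                Partition(p["plugin"], p["count"], p["base"])
                for p in doc["partitions"]
            ]
        )
        expected = allocate_layout([(p.plugin, p.count) for p in layout.partitions])
        if [p.base for p in layout.partitions] != [
            p.base for p in expected.partitions
        ]:
            raise ConfigurationError("layout bases violate the padding recurrence")
        return layout


def allocate_layout(partitions: Sequence[tuple[str, int]]) -> IDLayout:
    """Assign word-padded base offsets to an ordered list of (plugin, count).

    Empty plugins occupy zero words; duplicate plugin names are rejected.
    """
    names = [name for name, _ in partitions]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate plugin name(s): {dupes}")
    out: list[Partition] = []
    base = 0
    for name, count in partitions:
        if count < 0:
            raise ConfigurationError(f"negative count for plugin {name!r}")
        out.append(Partition(name, count, base))
        base += padded_length(count)
    return IDLayout(out)


@dataclass
class SpikeBitVector:
    """Word-packed firing state: one bit per element, LSB-first within words.

    Bits at positions >= the owning layout's populated count stay 0; the
    word array length is exactly ``length_bits / 32``.
    """

    words: np.ndarray
    length_bits: int
    time_step: int = 0

    @classmethod
    def zeros(cls, length_bits: int, time_step: int = 0) -> "SpikeBitVector":
        if length_bits % WORD_BITS:
            raise ConfigurationError(
                f"bit-vector length {length_bits} is not a multiple of {WORD_BITS}"
            )
        return cls(
            words=np.zeros(length_bits // WORD_BITS, dtype=np.uint32),
            length_bits=length_bits,
            time_step=time_step,
        )

    def _check(self, index: int) -> None:
        if not 0 <= index < self.length_bits:
            raise IndexError(
                f"bit index {index} out of range [0, {self.length_bits})"
            )

    def set_bit(self, index: int) -> None:
        self._check(index)
        self.words[index // WORD_BITS] |= np.uint32(1 << (index % WORD_BITS))

    def clear_bit(self, index: int) -> None:
        self._check(index)
        self.words[index // WORD_BITS] &= np.uint32(
            ~(1 << (index % WORD_BITS)) & 0xFFFFFFFF
        )

    def get_bit(self, index: int) -> int:
        self._check(index)
        return int((self.words[index // WORD_BITS] >> (index % WORD_BITS)) & 1)

    def clear_all(self) -> None:
        self.words[:] = 0

    def set_from_indices(self, indices: np.ndarray | Sequence[int]) -> None:
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size == 0:
            return
        if idx.min() < 0 or idx.max() >= self.length_bits:
            raise IndexError("bit index out of range")
        np.bitwise_or.at(
            self.words, idx // WORD_BITS, np.uint32(1) << (idx % WORD_BITS).astype(np.uint32)
        )

    def to_indices(self) -> np.ndarray:
        """Ascending positions of all set bits."""
        bits = np.unpackbits(self.words.view(np.uint8), bitorder="little")
        return np.nonzero(bits)[0].astype(np.int64)

    def to_bool_array(self) -> np.ndarray:
        return np.unpackbits(self.words.view(np.uint8), bitorder="little").astype(bool)

    def popcount(self) -> int:
        return int(
            np.unpackbits(self.words.view(np.uint8), bitorder="little").sum()
        )

    def copy(self) -> "SpikeBitVector":
        return SpikeBitVector(self.words.copy(), self.length_bits, self.time_step)


def translate(
    scoped_id: int,
    layouts: dict[Scope, IDLayout],
    plugin: str,
    from_scope: Scope,
    to_scope: Scope,
) -> int:
    """Translate a populated ID between scopes for one plugin's elements.

    Each scope's layout contains a partition named ``plugin``; the element's
    offset within that partition is scope-invariant, so translation is a base
    swap.  Padding-hole IDs are rejected.
    """
    src = layouts[from_scope]
    part = src.partition_of(scoped_id)
    if part.plugin != plugin:
        raise ConfigurationError(
            f"ID {scoped_id} belongs to plugin {part.plugin!r}, not {plugin!r}"
        )
    offset = scoped_id - part.base
    dst = layouts[to_scope]
    return dst.base_of(plugin) + offset
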