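"""Deterministic named random streams.

All randomness in a simulation flows from one document/CLI seed through
named child streams (``generator``, ``connections``, ``stimulus/3`` ...),
so changing how one subsystem consumes randomness never reshuffles the
draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, name: str) -> int:
    """Stable 31-bit child seed derived from a root seed and a stream name."""
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) & 0x7FFFFFFF


def child_rng(seed: int, name: str) -> np.random.Generator:
    """PCG64 generator for the named stream of the given root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))])
    )
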