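"""Deterministic per-component random substreams.

One master seed drives every stochastic component. Each component derives
its own generator from a stable hash of its name, so adding or reordering
components never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the named component under a master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(int(seed), spawn_key=(key,))


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named component under a master seed."""
    return np.random.default_rng(substream_seed(seed, name))
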