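"""Seed fan-out: one user-visible seed, named substreams per stage."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of a master seed.

    The substream key is a CRC32 hash of the name, so streams for different
    stages are statistically independent and stable across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
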