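"""Seed management: one top-level seed, named substreams per operation."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for a named substream of a top-level seed.

    The stream key is derived from a CRC of the name so that adding a new
    stage never perturbs the draws of existing stages, and identical
    (seed, name, index) always yields identical draws.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, int(index)]))
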