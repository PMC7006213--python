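"""Deterministic seed derivation.

Every source of randomness in the package draws from a generator derived
from (master seed, stage tag [, extra ints]).  Tags are stable CRC32
hashes of short strings, so streams do not depend on evaluation order,
and two models evaluated under the same master seed consume identical
resample/fold index streams — the property paired comparisons rely on.
"""

from __future__ import annotations

import zlib

import numpy as np


def tag(name: str) -> int:
    return zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF


def rng_for(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Generator keyed by master seed, a stage name, and optional ints."""
    words = [int(seed) & 0x7FFFFFFF, tag(name), *[int(e) & 0x7FFFFFFF for e in extra]]
    return np.random.default_rng(np.random.SeedSequence(words))
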