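"""Deterministic child-seed derivation.

Every stochastic operation takes a seed and derives an independent
``numpy.random.Generator`` from the master seed plus a stable string tag, so
stages can be rerun independently and still reproduce the pipeline bitwise.
Tag order is part of the public contract: seeds are derived as
``(master_seed, crc32(tag))``.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Generator for operation ``tag`` under master ``seed``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def child_seed(seed: int, tag: str) -> int:
    """Derived integer seed (< 2**31) for libraries that take one number."""
    return int((int(seed) & 0x7FFFFFFF) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF
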