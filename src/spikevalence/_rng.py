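"""Seeded random substreams.

All randomness in the package flows from a single integer seed. Each stage
(simulate / reservoir / evaluation / ...) draws from its own named substream so
that changing one stage's consumption pattern does not perturb the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named child seed sequence from a top-level integer seed."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator on the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))
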