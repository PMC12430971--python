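"""Named-stream random number generation.

All stochastic components derive their generator from a single root seed plus a
tuple of stream names, so any module's data can be regenerated independently of
the order in which other modules consumed randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the stream identified by ``names`` under ``seed``.

    The same (seed, names) pair always yields the same stream; distinct name
    tuples yield statistically independent streams (SeedSequence spawn keys).
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
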