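"""Named substreams from one root seed.

Every stochastic stage draws from its own substream so that adding or
reordering stages does not silently shift another stage's random numbers.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, crc32(name))``.

    The CRC is masked to 31 bits so spawn keys stay small and portable.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    )
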