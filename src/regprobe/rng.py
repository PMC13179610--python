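"""Reproducible named random substreams.

All stochastic layers of the package (instance generation, realization
sampling, tie-breaking) derive their generators from one master seed plus a
tuple of names, so each layer is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """Return a generator seeded by ``master_seed`` and a name path.

    The same ``(master_seed, *names)`` tuple always yields an identical
    stream; distinct name paths yield statistically independent streams.
    Names may be strings or integers (e.g. replicate indices).
    """
    keys = [zlib.crc32(str(n).encode("utf-8")) for n in names]
    entropy = [int(master_seed) & 0x7FFFFFFF, *keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
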