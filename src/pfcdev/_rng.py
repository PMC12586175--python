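"""Named, reproducible random substreams.

All stochastic stages derive their generator from one global seed plus a
stage name, so bootstraps and permutation tests are reproducible
independently of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the global `seed`.

    The stream key is a CRC32 of the stage name, which is stable across
    runs and Python versions (unlike `hash`).
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)
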