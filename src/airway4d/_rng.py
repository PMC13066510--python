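"""Named random substreams.

All randomness in the package flows from a single master seed.  A substream
is addressed by a sequence of names (e.g. ``("demographics",)`` or
``("frame_noise", "P007", "open", 3)``); the names are hashed into a
``SeedSequence`` spawn key, so any stage can be re-derived in isolation
without replaying the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """Generator for the substream addressed by ``names`` under ``master_seed``."""
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                spawn_key=tuple(_key(n) for n in names))
    return np.random.default_rng(ss)
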