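"""Named random substreams.

Every stochastic operation in the package draws from a Generator keyed by
(seed, *labels).  Labels are stable strings/ints hashed into SeedSequence
spawn keys, so adding a new purpose, animal, or session never perturbs the
stream of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Deterministic Generator for the substream named by ``labels``."""
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=tuple(_key(p) for p in labels))
    return np.random.Generator(np.random.PCG64(ss))
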