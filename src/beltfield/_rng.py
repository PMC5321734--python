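"""Deterministic, order-independent random substreams.

Every source of randomness in the package derives from a master seed plus a
tuple of string/int keys (typically ``(unit_id, stage)``), so adding or
reordering units never changes another unit's draws.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator seeded from ``(master_seed, *keys)``."""
    entropy = [int(master_seed) & 0xFFFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            entropy.append(int(key) & 0xFFFFFFFF)
        else:
            entropy.append(crc32(str(key).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))
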