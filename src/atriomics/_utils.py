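"""Small shared helpers: seeding and warning capture."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed by stable hashing.

    Uses CRC32 of the stage name so the derivation is identical across
    platforms and Python processes (``hash()`` is salted and unsuitable).
    Result is kept below 2**31.
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return int((int(global_seed) ^ h) % (2**31 - 1))


def rng_for(seed: int, stage: str | None = None) -> np.random.Generator:
    if stage is not None:
        seed = stage_seed(seed, stage)
    return np.random.default_rng(seed)
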