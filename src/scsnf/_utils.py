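"""Shared helpers: reproducible seed derivation and logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("scsnf")


def child_seed_sequence(master: int, *key: str | int) -> np.random.SeedSequence:
    """Derive an independent SeedSequence from a master seed and a stage key.

    String keys are hashed with CRC32 so the derivation is stable across
    processes and Python hash randomization.
    """
    words = [int(master) & 0x7FFFFFFF]
    for k in key:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(k) & 0x7FFFFFFF)
    return np.random.SeedSequence(words)


def rng_for(master: int, *key: str | int) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(master, *key))


def small_seed(master: int, *key: str | int) -> int:
    """A single 31-bit integer seed for libraries that take an int."""
    return int(child_seed_sequence(master, *key).generate_state(1)[0] & 0x7FFFFFFF)
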