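"""Hierarchical, reproducible seed derivation.

Every source of randomness in the package flows from one master seed through
``child_seed(master, *path)``, where ``path`` is a sequence of strings/ints
naming the consumer (e.g. ``("size", 800, "rep", 2)``).  The derivation is a
``numpy.random.SeedSequence`` with a spawn key built from stable CRC32 hashes
of the path components, so any experiment cell can be re-executed in
isolation from its logged path.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def child_seed(master_seed: int, *path) -> np.random.SeedSequence:
    """Derive a SeedSequence for the consumer named by ``path``."""
    return np.random.SeedSequence(int(master_seed) & 0x7FFFFFFF,
                                  spawn_key=tuple(_key_part(p) for p in path))


def child_rng(master_seed: int, *path) -> np.random.Generator:
    """Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *path))
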