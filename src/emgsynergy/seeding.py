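"""Deterministic hierarchical seed derivation.

Every stochastic operation in the package draws from a generator derived
from a master seed plus a stable path of string/int keys (stage, subject,
trial, repetition ...).  Adding repetitions or stages therefore never
perturbs existing random streams, and a full run is a pure function of the
master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]

_MOD = 2**31 - 1


def derive_seed(master_seed: int, *path) -> int:
    """Derive a child seed (< 2**31) from a master seed and a key path."""
    key = "/".join(str(p) for p in path)
    digest = zlib.crc32(key.encode("utf-8"))
    return int((int(master_seed) * 2654435761 + digest) % _MOD)


def derive_rng(master_seed: int, *path) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *path))
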