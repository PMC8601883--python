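"""Deterministic seed derivation.

All randomness in the package flows from a single integer master seed.
Named child streams are derived with ``numpy.random.SeedSequence`` spawn
keys built from CRC32 hashes of string tokens, so any cell of any grid is
recomputable in isolation and adding a stage never perturbs another
stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master: int, *tokens: object) -> np.random.SeedSequence:
    key = tuple(zlib.crc32(str(t).encode("utf-8")) for t in tokens)
    return np.random.SeedSequence(int(master), spawn_key=key)


def child_rng(master: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *tokens))
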