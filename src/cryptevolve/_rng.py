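"""Seed handling: one global seed expanded into named, order-independent substreams."""

from __future__ import annotations

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for a named substream of ``seed``.

    Streams are independent of the order in which they are requested, so
    adding a new consumer of randomness does not perturb existing ones.
    """
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    # stable string hash (Python's hash() is salted per-process)
    h = 2166136261
    for byte in str(key).encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h
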