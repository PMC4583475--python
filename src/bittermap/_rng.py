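"""Hierarchical seeded random streams.

Every stochastic operation in the package derives its generator from a base
integer seed plus a stable string tag, so sub-sampling one stage never
perturbs another.
"""
from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of string tags."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode("utf8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))
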