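"""Seeded random-generator hierarchy.

Every stochastic stage draws from a substream derived from the run seed and
the stage name, so adding or reordering stages never perturbs another
stage's stream and a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit sub-seed for a named stage."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for stage ``name`` under run ``seed``."""
    return np.random.default_rng(stage_seed(seed, name))
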