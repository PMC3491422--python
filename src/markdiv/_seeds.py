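"""Deterministic per-stage RNG derivation from a single master seed.

Each pipeline stage gets its own :class:`numpy.random.Generator`, derived
from the master seed and a stage label, so stages are independently
reproducible and reordering or skipping stages never perturbs another
stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """A stable 31-bit child seed for a named stage."""
    mix = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(mix,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded deterministically from (master_seed, stage)."""
    return np.random.default_rng(stage_seed(master_seed, stage))
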