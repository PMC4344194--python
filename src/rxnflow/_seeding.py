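"""Deterministic seed hierarchy.

A single master seed plus an integer path (e.g. ``(model_index, sample,
stage)``) maps to an independent child stream, so any individual network,
thermodynamic assignment or initialization can be regenerated in isolation.
"""

from __future__ import annotations

import numpy as np


def child_seed(master_seed: int, *path: int) -> int:
    """A reproducible 31-bit child seed for the given path."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Generator seeded from :func:`child_seed` of the same path."""
    return np.random.default_rng(child_seed(master_seed, *path))
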