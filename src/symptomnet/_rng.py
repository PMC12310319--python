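"""Seed plumbing: every stochastic routine accepts either an integer
seed, None, or an already-spawned numpy SeedSequence, and derives its
own child streams from a SeedSequence hierarchy so replicates are
independent and order-insensitive."""

from __future__ import annotations

import numpy as np

__all__ = ["as_seed_sequence", "seed_record"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def seed_record(seed) -> int | None:
    """Integer form of a seed for result metadata (None if not an int)."""
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return None
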