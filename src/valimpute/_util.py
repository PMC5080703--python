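"""Small shared helpers: rounding and RNG stream handling.

All randomness in the package flows through :class:`numpy.random.Generator`
objects.  Public entry points accept either an integer seed, a
``SeedSequence`` or a ready ``Generator``; internally a single
``SeedSequence`` is spawned into named child streams so that every stage
(data generation, resampling, each imputation copy, permutations) draws
from its own independent, reproducible stream.
"""

from __future__ import annotations

import numpy as np


def round_half_even(x: float) -> int:
    """Round to the nearest integer, ties to the even neighbour."""
    return int(np.rint(x))


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if seed is None:
        return np.random.SeedSequence()
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        # derive a child sequence from the generator so caller state advances
        return np.random.SeedSequence(int(seed.integers(0, 2**31 - 1)))
    return np.random.SeedSequence(int(seed))


def as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(as_seed_sequence(seed))


def spawn(seed, n: int) -> list[np.random.SeedSequence]:
    """Split a seed into ``n`` independent child sequences."""
    return as_seed_sequence(seed).spawn(n)
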