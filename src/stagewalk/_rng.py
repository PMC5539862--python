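"""Seed-derivation helpers.

One master seed drives the whole pipeline; every stage / repetition gets an
independent stream derived from ``(seed, *keys)`` so that changing the number
of repetitions never perturbs earlier ones.
"""

from __future__ import annotations

import numpy as np

# fixed per-purpose stream tags, so independent stages never collide
STREAM_COHORT = 0
STREAM_WINDOWS = 1
STREAM_PROJECTIONS = 2
STREAM_BOOTSTRAP = 3
STREAM_SPLIT = 4
STREAM_NN = 5
STREAM_DEPTH = 6


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *keys)``."""
    if seed is None:
        raise ValueError("a seed is required; unseeded runs are not supported")
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def spawn_seeds(seed: int, n: int, *keys: int) -> np.ndarray:
    """Return ``n`` child integer seeds (< 2**31) for external libraries."""
    rng = derive_rng(seed, *keys)
    return rng.integers(0, 2**31 - 1, size=n)
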