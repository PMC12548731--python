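"""Deterministic, platform-stable seed derivation.

Every stochastic operation in the package is reproducible from a base seed
plus an integer key path (e.g. a matrix index).  Derivation goes through
``numpy.random.SeedSequence`` with the key path as the spawn key, which is
a documented, platform-independent counter-based scheme.
"""

from __future__ import annotations

import numpy as np

__all__ = ["seed_sequence", "rng_for", "child_seed"]


def seed_sequence(base_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in key))


def rng_for(base_seed: int, *key: int) -> np.random.Generator:
    """A fresh PCG64 generator for (base_seed, key...)."""
    return np.random.default_rng(seed_sequence(base_seed, *key))


def child_seed(base_seed: int, *key: int) -> int:
    """A derived 31-bit integer seed, stable across platforms."""
    return int(seed_sequence(base_seed, *key).generate_state(1, np.uint32)[0] >> 1)
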