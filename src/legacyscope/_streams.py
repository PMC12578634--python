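"""Named, counter-based child seed streams.

Every source of randomness in the package derives from one global integer seed
through a named stream ("stage:operation"), so each stage is reproducible
independently of call order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "child_seed"]


def child_seed_sequence(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the named stream derived from the global seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf8"))])


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stream derived from the global seed."""
    return np.random.default_rng(child_seed_sequence(seed, name))


def child_seed(seed: int, name: str) -> int:
    """A plain integer child seed (< 2**31) for APIs that take an int seed."""
    return int(child_seed_sequence(seed, name).generate_state(1)[0] % (2**31))
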