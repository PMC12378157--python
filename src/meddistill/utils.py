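"""Seeding helpers: one global seed, named deterministic substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    All randomness in the package flows through here so that a single run
    seed reproduces every component (data, init, shuffling) independently:
    changing what one component draws never perturbs another.
    """
    keys = tuple(zlib.crc32(str(n).encode("utf8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))


def child_seed(seed: int, *names: object) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
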