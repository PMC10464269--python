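"""Reproducible named random substreams.

All stochastic code in the package draws from a single master seed through
named substreams, so any participant or pipeline stage can be regenerated in
isolation and whole runs are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key(names: tuple) -> tuple[int, ...]:
    # crc32 is stable across platforms and Python versions, unlike hash()
    return tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)


def substream(master_seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Distinct name tuples give statistically independent streams; the same
    (master_seed, names) pair always returns an identical stream.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=_key(names)))


def substream_seed(master_seed: int, *names) -> int:
    """A derived 31-bit integer seed for the named substream."""
    ss = np.random.SeedSequence(master_seed, spawn_key=_key(names))
    return int(ss.generate_state(1)[0] % (2**31))
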