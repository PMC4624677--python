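"""Deterministic random-stream management.

All stochastic code in the package draws from :func:`substream`, which maps a
single user-facing integer seed plus a tuple of string/int keys onto an
independent ``numpy.random.Generator``. Sub-streams are reproducible in
isolation: generating the trajectory for (seed=7, "trajectory", 3) yields the
same numbers whether or not any other stream was consumed first.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"stream key must be int or str, got {type(key).__name__}")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``keys``.

    Parameters
    ----------
    seed
        Master seed (any Python int).
    *keys
        Hierarchical stream identifiers, e.g. ``("trajectory", animal_index)``.
    """
    entropy = (int(seed),) + tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
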