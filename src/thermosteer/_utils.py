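"""Shared helpers: angle arithmetic in degrees and seeded RNG substreams."""

from __future__ import annotations

import hashlib

import numpy as np


def wrap_angle(deg):
    """Wrap angles to the interval (-180, 180] degrees."""
    a = np.asarray(deg, dtype=float)
    out = 180.0 - (180.0 - a) % 360.0
    if np.isscalar(deg):
        return float(out)
    return out


def angle_between(deg_a, deg_b):
    """Unsigned angle in [0, 180] between two directions given in degrees."""
    d = np.abs(wrap_angle(np.asarray(deg_b, dtype=float) - np.asarray(deg_a, dtype=float)))
    if np.isscalar(deg_a) and np.isscalar(deg_b):
        return float(d)
    return d


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from a master seed.

    The stream identity is the master seed plus a stable hash of the string
    representation of ``keys``, so independent pipeline stages draw from
    non-overlapping streams without coordinating counters.
    """
    h = hashlib.sha256(("/".join(str(k) for k in keys)).encode()).digest()
    salt = int.from_bytes(h[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt]))
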