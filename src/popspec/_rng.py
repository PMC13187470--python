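"""Deterministic child RNG streams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream keyed by (master seed, stage label).

    The label is hashed with CRC32 so streams are stable across runs and
    insensitive to the order stages are executed in.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
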