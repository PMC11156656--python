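"""Seed handling: one user seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Streams are keyed by CRC-32 of the name, so each stage (residues,
    calibration, blanks, spikes, risk ...) can be regenerated on its own
    without replaying the others.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
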