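"""Deterministic stream splitting for all stochastic components.

One user-facing seed controls every draw in the package. Independent
streams are derived with ``derive_rng(seed, label)``: the label is hashed
with CRC-32 and combined with the seed through ``numpy.random.SeedSequence``,
so adding a new consumer never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng"]


def derive_rng(seed: int | None, label: str) -> np.random.Generator:
    """Return a Generator for the stream named ``label`` under ``seed``.

    ``seed=None`` gives OS entropy (non-reproducible); any integer seed makes
    every labelled stream bit-reproducible.
    """
    if seed is None:
        return np.random.default_rng()
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
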