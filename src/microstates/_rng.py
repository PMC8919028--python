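"""Deterministic random-stream derivation.

All stochastic stages derive their generator from one global integer seed
plus a tuple of string labels naming the stage (and, where needed, the
batch).  The labels are hashed with CRC-32 into a ``spawn_key`` for
:class:`numpy.random.SeedSequence`, so every stage is independently
reproducible without threading generator state through the pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a generator for the stream named by ``labels`` under ``seed``.

    The same ``(seed, labels)`` pair always yields an identical stream;
    distinct label paths yield statistically independent streams.
    """
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
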