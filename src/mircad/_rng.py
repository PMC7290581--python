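"""Named random substreams derived from one global seed.

Every stochastic operation in the package draws from a substream keyed by
(seed, operation name), so individual stages are reproducible in isolation
and adding a new stage never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of global `seed`."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
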