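"""Seeded random-number substreams.

One root seed drives a whole run; each stochastic stage (QTN selection,
environmental noise, penetrance draws, marker and individual subsampling)
gets its own independent substream so that changing one stage never perturbs
the draws of another.
"""
from __future__ import annotations

import numpy as np

# Fixed substream keys. Stable across versions: they are part of the
# reproducibility contract.
QTN_SELECTION = 0
NOISE = 1
PENETRANCE = 2
MARKERS = 3
INDIVIDUALS = 4
FIXTURE = 5

SeedLike = "int | np.random.Generator"


def substream(seed: int | np.random.Generator, key: int) -> np.random.Generator:
    """Return the generator for stage ``key`` under root ``seed``.

    A ``numpy.random.Generator`` passed directly is returned unchanged,
    letting callers manage their own stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
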