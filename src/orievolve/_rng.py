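"""Seed-stream derivation.

Every stochastic operation in the package accepts either an integer seed or a
ready-made :class:`numpy.random.Generator`.  Integer seeds are expanded into
independent per-stage streams with :class:`numpy.random.SeedSequence` spawn
keys, so each pipeline stage is reproducible on its own: running the read
simulator with seed 7 gives the same reads whether or not the library was
regenerated first.
"""

from __future__ import annotations

import numpy as np

# Registry of named sub-streams.  Adding a stage appends a new id; existing
# ids are frozen so published seeds stay stable.
_STREAMS = {
    "reference": 0,
    "library": 1,
    "phenotype": 2,
    "selection": 3,
    "checkerboard": 4,
    "reads": 5,
    "dpcr": 6,
    "growth": 7,
    "misc": 8,
}

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def stream_rng(seed, stream: str = "misc", index: int = 0) -> np.random.Generator:
    """Return a Generator for the named stream derived from ``seed``.

    ``index`` distinguishes repeated uses of the same stream (e.g. the two
    sequencing runs of the unselected and selected populations).
    Generators and SeedSequences are passed through / consumed directly.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        if seed is None:
            seed = 0
        ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream], index))
    return np.random.default_rng(ss)
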