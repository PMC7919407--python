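"""Deterministic random-number substreams.

Every stochastic stage of the simulator draws from its own generator, derived
from one master seed and a stage key.  The key is ``(master_seed, crc32(stage
name), index)`` fed to :class:`numpy.random.SeedSequence`, so adding a new
stage (or changing how many numbers one stage consumes) never perturbs the
draws of any other stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for one named stage of a seeded computation.

    Parameters
    ----------
    master_seed : int
        The experiment-level seed.
    stage : str
        Stable stage name, e.g. ``"truth"`` or ``"observations"``.
    index : int
        Optional per-item index (e.g. an image index) for stages that need an
        independent stream per item.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key, int(index)))
    return np.random.default_rng(seq)
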