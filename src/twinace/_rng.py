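"""Named, independent RNG streams.

Each stochastic stage of the pipeline (liability simulation, measurement,
missingness, ages, bootstrap, ...) draws from its own stream derived from a
single base seed, so changing the number of draws in one stage does not
perturb any other stage.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for *stage*, deterministically derived from *seed*.

    The stream key is a CRC of the stage name, so streams are stable across
    releases as long as the stage names are.
    """
    if seed is None:
        raise ValueError("an explicit seed is required; no implicit default")
    key = zlib.crc32(stage.encode("utf-8")) % _MOD
    return np.random.default_rng(np.random.SeedSequence([int(seed) % _MOD, key]))


def substream(rng_seed: int, stage: str, index: int) -> np.random.Generator:
    """A numbered child stream (e.g. one per bootstrap replicate)."""
    key = zlib.crc32(stage.encode("utf-8")) % _MOD
    return np.random.default_rng(
        np.random.SeedSequence([int(rng_seed) % _MOD, key, int(index) % _MOD])
    )
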