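"""Named random substreams derived from a single root seed.

Every stochastic step in the pipeline (cohort simulation, fold shuffling,
minority resampling, weight initialization) draws from its own substream so
components are independently reproducible: rerunning one step never perturbs
the randomness of another.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def substream_seed(root_seed: int, *names: str) -> int:
    """Derive a child seed (< 2**31) from a root seed and a path of names."""
    keys = [zlib.crc32(name.encode("utf-8")) for name in names]
    ss = np.random.SeedSequence([int(root_seed) & MAX_SEED, *keys])
    return int(ss.generate_state(1, np.uint32)[0]) & MAX_SEED


def rng_for(root_seed: int, *names: str) -> np.random.Generator:
    """Generator seeded on the named substream of ``root_seed``."""
    if names:
        return np.random.default_rng(substream_seed(root_seed, *names))
    return np.random.default_rng(int(root_seed) & MAX_SEED)
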