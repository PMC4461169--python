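"""Deterministic seed derivation for pipeline stages.

Every random operation in the pipeline draws from a Generator derived from
(master seed, stage name), so a whole run is reproducible from one integer
and stage outputs never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """A stable child seed (< 2**31) for ``stage`` under ``master_seed``."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), tag, int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derive_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), tag, int(index)])
    )
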