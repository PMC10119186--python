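"""Deterministic derivation of per-stage child seeds from one global seed.

Every stochastic stage of the pipeline draws from its own
:class:`numpy.random.Generator`, seeded by a child seed derived from the single
user-supplied integer seed and a stage name.  The scheme is
``SeedSequence([seed, crc32(stage)])``, so child streams are independent,
reproducible, and stable across processes and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _stage_code(stage: str) -> int:
    return zlib.crc32(stage.encode("utf-8"))


def child_seed(seed: int, stage: str) -> int:
    """Return a deterministic 31-bit child seed for ``stage``."""
    ss = np.random.SeedSequence([int(seed), _stage_code(stage)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator seeded for ``stage``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _stage_code(stage)])
    )
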