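"""Deterministic fan-out of one global seed into per-stage seeds.

A stage seed is ``int(sha256(f"{seed}:{stage}")[:8], 16) % 2**31`` — stable
across platforms and Python versions, so any stage can be re-run in
isolation from the global seed alone.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
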