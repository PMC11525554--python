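"""Seed fan-out: one user-facing seed, independent named substreams."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(base: int, name: str) -> int:
    """Stable sub-seed (< 2**31) for the named stage of a run.

    Adding a stage never perturbs another stage's stream, because each
    stream depends only on (base, name).
    """
    digest = hashlib.sha256(f"{int(base)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def substream(base: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base, name))
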