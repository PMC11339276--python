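"""Seed management: every stochastic stage derives a named substream from a master seed."""

from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def child_seed(seed: int, *names: str | int) -> int:
    """Deterministically derive a small integer seed for a named substream."""
    h = np.int64(int(seed) % _MOD)
    for name in names:
        for ch in str(name).encode():
            h = (h * np.int64(131) + np.int64(ch)) % np.int64(_MOD)
    return int(h)


def rng_for(seed: int, *names: str | int) -> np.random.Generator:
    """A Generator for the substream identified by ``names`` under ``seed``."""
    return np.random.default_rng(child_seed(seed, *names))
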