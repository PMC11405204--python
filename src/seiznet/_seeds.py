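"""Deterministic seed derivation.

A single experiment-level seed spawns independent child seeds keyed by
(well index, day index) through :class:`numpy.random.SeedSequence` with
an explicit ``spawn_key``. The rule is position-stable: adding wells or
days never perturbs the stream of an existing (well, day) cell.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(root_seed: int, *key: int) -> int:
    """Derive a 31-bit child seed from ``root_seed`` and an index key."""
    ss = np.random.SeedSequence(int(root_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the same child stream."""
    ss = np.random.SeedSequence(int(root_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
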