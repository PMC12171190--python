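"""Hierarchical, counter-based seed derivation.

All randomness in the package flows from a single integer seed. Sub-streams
are derived from ``(seed, *path)`` where ``path`` is a mix of strings and
integers identifying the consumer; deriving stream ``(seed, "sample", k)``
is independent of how many other streams exist, so adding samples or
consumers never perturbs earlier draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed_sequence", "rng_for", "child_seed"]


def _token_to_int(token: str | int) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def derive_seed_sequence(seed: int, *path: str | int) -> np.random.SeedSequence:
    """Return a ``SeedSequence`` for the sub-stream identified by ``path``."""
    entropy = [int(seed) & 0xFFFFFFFFFFFFFFFF] + [_token_to_int(t) for t in path]
    return np.random.SeedSequence(entropy)


def rng_for(seed: int, *path: str | int) -> np.random.Generator:
    """Return a fresh ``Generator`` for the sub-stream identified by ``path``."""
    return np.random.Generator(np.random.PCG64(derive_seed_sequence(seed, *path)))


def child_seed(seed: int, *path: str | int) -> int:
    """Collapse a sub-stream identity into a single 32-bit integer seed."""
    return int(derive_seed_sequence(seed, *path).generate_state(1)[0])
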