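"""Stable seed fan-out.

A single master seed is expanded into per-stage / per-bin / per-replicate /
per-pair seeds by hashing the key tuple, so pipelines are bit-reproducible
regardless of execution order or parallelism.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, *keys) -> int:
    """Deterministic 31-bit seed derived from a master seed and a key path."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master_seed)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(str(k).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)


def child_rng(master_seed: int, *keys):
    import numpy as np

    return np.random.default_rng(child_seed(master_seed, *keys))
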