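"""Stable seed derivation.

A single master seed drives every stochastic stage; per-stage and
per-species seeds are derived by hashing the master seed with string keys,
so adding species or reordering stages never perturbs unrelated draws.
"""

from __future__ import annotations

import hashlib


def derived_seed(master: int, *keys: object) -> int:
    """Deterministic 31-bit seed from a master seed and string-able keys."""
    h = hashlib.blake2s(digest_size=8)
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(str(k).encode())
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)
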