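"""Deterministic seed derivation.

Every stochastic step in the pipeline draws from a numpy Generator whose seed
is derived from a single experiment seed plus a structured tag (assay id,
method name, bootstrap index, ...).  Derivation goes through BLAKE2 so that
substreams are statistically independent and paired comparisons (same tag
structure, different method) stay paired across runs.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31 - 1  # keep derived seeds comfortably below 2**31


def derive_seed(*parts: object) -> int:
    """Derive a reproducible 31-bit integer seed from arbitrary parts.

    Parts are rendered with ``repr`` and joined, so ``derive_seed(7, "smn", 3)``
    is stable across sessions and platforms.
    """
    payload = "\x1f".join(repr(p) for p in parts).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % _MOD
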