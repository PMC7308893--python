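"""Deterministic seed fan-out.

One user-facing seed is expanded into independent per-stage seeds by
hashing ``(master, label)``.  Hash-based derivation keeps stages
decorrelated (unlike ``master + i`` offsets) and adding a new stage never
shifts the streams of existing ones.  Derived seeds stay below 2**31 so
they are valid for every consumer (numpy Generators, scikit-learn
``random_state``).
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, label: str) -> int:
    """Derive a stage seed from a master seed and a stage label."""
    payload = f"{int(master)}:{label}".encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)
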