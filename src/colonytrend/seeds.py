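"""Deterministic seed derivation.

A single user-facing seed fans out into independent per-stage (and
per-colony) seeds via a stable hash, so adding or reordering stages never
perturbs the random stream of another stage.
"""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, *labels: str) -> int:
    """Derive a stable 31-bit seed from ``base_seed`` and a label path.

    The same ``(base_seed, labels)`` pair always yields the same seed, on any
    platform and Python version (unlike the builtin ``hash``).
    """
    key = ":".join([str(int(base_seed)), *labels]).encode("utf-8")
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)
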