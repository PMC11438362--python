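"""Small shared helpers: deterministic rounding and seed derivation."""

from __future__ import annotations

import hashlib
import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; the exact-count
    arithmetic of the simulator (arm sizes, winter counts, missing-day counts)
    needs the deterministic "0.5 rounds up" convention instead.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def derive_seed(base_seed: int, *parts) -> int:
    """Deterministic 31-bit child seed from a base seed and context labels.

    Hashing ``(base_seed, *parts)`` decouples the random streams of different
    scenario cells and replications: changing the replication index or cell
    label gives an unrelated stream, while the same tuple always reproduces
    the same stream.
    """
    payload = repr((int(base_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
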