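"""Small shared helpers (seed derivation, rounding)."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, *keys: object) -> int:
    """Derive a deterministic child seed from a global seed and stage keys.

    Stage keys (strings / ints) are hashed with crc32 so a pipeline stage can
    be re-run in isolation with the same stream it had inside a full run.
    The result always fits in a signed 32-bit integer.
    """
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def round_half_away(x: float) -> int:
    """round() with the half-away-from-zero convention (for mask cell counts)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))
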